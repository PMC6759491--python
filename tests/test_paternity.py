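"""Tests for likelihood-ratio paternity assignment and threshold calibration."""

import math

import numpy as np
import pytest

from crosskit.genotypes import AlleleFrequencyTable, LineGenotype, MarkerPanel
from crosskit.paternity import (
    ConfidenceThresholds,
    ErrorModel,
    NO_ERROR,
    PaternityAssignment,
    assign_paternity,
    detect_reciprocals,
    lod_score,
    simulate_confidence_thresholds,
    transition_prob,
)
from crosskit.simulate import default_loci_spec, simulate_dh_panel, simulate_interpollination
from crosskit.genotypes import allele_frequencies

from conftest import dh_line

A, B, C = 100, 103, 106

ONE_LOCUS_FREQS = AlleleFrequencyTable(
    {"L1": {A: 0.75, B: 0.25}}, n_individuals=10
)


def _freqs_8loci(fA=0.75, fB=0.25):
    loci = [f"L{i}" for i in range(1, 9)]
    return AlleleFrequencyTable({l: {A: fA, B: fB} for l in loci}, n_individuals=10)


def wide_thresholds(strict=0.0, relaxed=-1.0):
    return ConfidenceThresholds(
        strict_lod=strict, relaxed_lod=relaxed, strict_delta=strict,
        relaxed_delta=relaxed, n_progeny=0, n_candidates=0, prop_sampled=1.0,
        error=NO_ERROR,
    )


# ---------------------------------------------------------------------------
# transition_prob


def test_transition_mendelian_homozygote_trio():
    p = transition_prob((A, B), (A, A), (B, B), ONE_LOCUS_FREQS, "L1", NO_ERROR)
    assert p == 1.0


def test_transition_father_absent_integrates_frequencies():
    p = transition_prob((A, B), (A, A), None, ONE_LOCUS_FREQS, "L1", NO_ERROR)
    assert p == pytest.approx(0.25)  # freq of B


def test_transition_likelihood_ratio_is_four():
    num = transition_prob((A, B), (A, A), (B, B), ONE_LOCUS_FREQS, "L1", NO_ERROR)
    den = transition_prob((A, B), (A, A), None, ONE_LOCUS_FREQS, "L1", NO_ERROR)
    assert num / den == pytest.approx(4.0)


def test_transition_excluded_trio_is_zero():
    p = transition_prob((A, B), (A, A), (C, C), ONE_LOCUS_FREQS, "L1", NO_ERROR)
    assert p == 0.0


def test_transition_error_makes_exclusion_positive():
    err = ErrorModel(typed_rate=1.0, mistype_rate=0.002)
    p = transition_prob((A, B), (A, A), (C, C), ONE_LOCUS_FREQS, "L1", err)
    assert 0.0 < p < 0.01


def test_transition_heterozygous_parents():
    # mother A/B x father A/B -> offspring A/A with probability 1/4
    p = transition_prob((A, A), (A, B), (A, B), ONE_LOCUS_FREQS, "L1", NO_ERROR)
    assert p == pytest.approx(0.25)


# ---------------------------------------------------------------------------
# lod_score


def _trio_8loci():
    loci = [f"L{i}" for i in range(1, 9)]
    mother = dh_line("mo", [A] * 8, loci)
    father = dh_line("fa", [B] * 8, loci)
    off = LineGenotype(
        "off", {l: (A, B) for l in loci}, role="offspring", maternal_id="mo"
    )
    return loci, mother, father, off


def test_lod_eight_loci_of_ln4():
    loci, mother, father, off = _trio_8loci()
    res = lod_score(off, mother, father, _freqs_8loci(), NO_ERROR)
    assert res.lod == pytest.approx(8 * math.log(4.0))
    assert res.n_typed == 8
    assert res.n_mismatch == 0
    assert res.evaluable


def test_lod_exclusion_is_minus_infinity_at_zero_error():
    loci, mother, _, off = _trio_8loci()
    stranger = dh_line("st", [C] + [B] * 7, loci)
    res = lod_score(off, mother, stranger, _freqs_8loci(), NO_ERROR)
    assert res.lod == -math.inf
    assert res.n_mismatch == 1


def test_lod_not_evaluable_below_min_typed():
    loci, mother, father, off = _trio_8loci()
    off7 = LineGenotype(
        "off7",
        {**off.genotype, "L8": None},
        role="offspring",
        maternal_id="mo",
    )
    res = lod_score(off7, mother, father, _freqs_8loci(), NO_ERROR, min_typed_loci=8)
    assert not res.evaluable
    res7 = lod_score(off7, mother, father, _freqs_8loci(), NO_ERROR, min_typed_loci=7)
    assert res7.evaluable


def test_lod_self_candidate_flagged():
    loci, mother, _, _ = _trio_8loci()
    selfed = LineGenotype(
        "s", {l: (A, A) for l in loci}, role="offspring", maternal_id="mo"
    )
    res = lod_score(selfed, mother, mother, _freqs_8loci(), NO_ERROR)
    assert res.is_self


# ---------------------------------------------------------------------------
# threshold simulation


def test_thresholds_ordering_and_determinism(dh36):
    panel, freqs = dh36
    kw = dict(
        n_candidates=36, n_progeny=2000, prop_sampled=1.0,
        error=ErrorModel(0.998, 0.002), seed=11,
    )
    t1 = simulate_confidence_thresholds(freqs, **kw)
    t2 = simulate_confidence_thresholds(freqs, **kw)
    assert t1.strict_lod >= t1.relaxed_lod
    assert t1.strict_delta >= t1.relaxed_delta
    assert (t1.strict_lod, t1.relaxed_lod, t1.strict_delta) == (
        t2.strict_lod,
        t2.relaxed_lod,
        t2.strict_delta,
    )


def test_thresholds_high_information_panel(dh36):
    # fully sampled, highly polymorphic: nearly every best candidate is the
    # true father, so the strict cut-off sits at/below typical father LODs
    panel, freqs = dh36
    t = simulate_confidence_thresholds(
        freqs, n_candidates=36, n_progeny=2000, error=NO_ERROR, seed=3
    )
    assert math.isfinite(t.strict_lod)
    assert t.strict_lod < 8 * math.log(4.0)
    assert t.strict_delta <= t.strict_lod


def test_thresholds_monomorphic_error():
    freqs = AlleleFrequencyTable({"L1": {A: 1.0}}, n_individuals=5)
    with pytest.raises(ValueError, match="monomorphic"):
        simulate_confidence_thresholds(freqs, n_candidates=10, n_progeny=100, seed=1)


# ---------------------------------------------------------------------------
# assignment


def _candidate_panel(extra=()):
    loci = [f"L{i}" for i in range(1, 9)]
    lines = [
        dh_line("mo", [A] * 8, loci),
        dh_line("fa", [B] * 8, loci),
        dh_line("st", [C] + [B] * 7, loci),
    ] + list(extra)
    return MarkerPanel(loci=loci, lines=lines)


def _freqs_3alleles():
    loci = [f"L{i}" for i in range(1, 9)]
    return AlleleFrequencyTable(
        {l: {A: 0.5, B: 0.25, C: 0.25} for l in loci}, n_individuals=10
    )


def test_assign_unique_father_strict():
    panel = _candidate_panel()
    off = LineGenotype(
        "o1", {l: (A, B) for l in panel.loci}, role="offspring", maternal_id="mo"
    )
    (res,) = assign_paternity([off], panel, _freqs_3alleles(), wide_thresholds(), NO_ERROR)
    assert res.assigned_father == "fa"
    assert res.confidence == "strict"
    assert res.maternal_ok
    assert not res.ambiguous_group


def test_assign_identical_candidates_ambiguous():
    loci = [f"L{i}" for i in range(1, 9)]
    twin = dh_line("fa2", [B] * 8, loci)
    panel = _candidate_panel(extra=[twin])
    off = LineGenotype(
        "o1", {l: (A, B) for l in loci}, role="offspring", maternal_id="mo"
    )
    (res,) = assign_paternity([off], panel, _freqs_3alleles(), wide_thresholds(), NO_ERROR)
    assert res.assigned_father is None
    assert sorted(res.ambiguous_group) == ["fa", "fa2"]


def test_assign_no_compatible_candidate_unassigned():
    loci = [f"L{i}" for i in range(1, 9)]
    panel = MarkerPanel(
        loci=loci, lines=[dh_line("mo", [A] * 8, loci), dh_line("st", [C] * 8, loci)]
    )
    off = LineGenotype(
        "o1", {l: (A, B) for l in loci}, role="offspring", maternal_id="mo"
    )
    (res,) = assign_paternity([off], panel, _freqs_3alleles(), wide_thresholds(), NO_ERROR)
    assert res.assigned_father is None
    assert res.confidence == "unassigned"


def test_assign_maternal_discrepancy_reported():
    panel = _candidate_panel()
    off = LineGenotype(
        "o1", {l: (B, C) for l in panel.loci}, role="offspring", maternal_id="mo"
    )
    (res,) = assign_paternity([off], panel, _freqs_3alleles(), wide_thresholds(), NO_ERROR)
    assert not res.maternal_ok
    assert res.assigned_father is None
    assert "maternal" in res.note


def test_assign_requires_recorded_mother():
    panel = _candidate_panel()
    off = LineGenotype("o1", {l: (A, B) for l in panel.loci}, role="offspring")
    with pytest.raises(ValueError, match="maternal_id"):
        assign_paternity([off], panel, _freqs_3alleles(), wide_thresholds(), NO_ERROR)


def test_assign_mismatch_blocks_confidence():
    # top candidate carries one excluded locus under nonzero error: no call
    loci = [f"L{i}" for i in range(1, 9)]
    panel = MarkerPanel(
        loci=loci, lines=[dh_line("mo", [A] * 8, loci), dh_line("st", [C] + [B] * 7, loci)]
    )
    off = LineGenotype(
        "o1", {l: (A, B) for l in loci}, role="offspring", maternal_id="mo"
    )
    err = ErrorModel(typed_rate=1.0, mistype_rate=0.01)
    (res,) = assign_paternity(
        [off], panel, _freqs_3alleles(), wide_thresholds(strict=-100, relaxed=-101), err
    )
    assert res.confidence == "unassigned"
    assert res.assigned_father is None


def test_true_father_lod_dominates_unrelated(dh36):
    # expectation property: true fathers outscore unrelated candidates
    panel, freqs = dh36
    offspring, truth = simulate_interpollination(panel, 30, seed=17)
    rng = np.random.default_rng(17)
    diffs = []
    for off in offspring[:1000]:
        mother = panel.by_id(off.maternal_id)
        father = panel.by_id(truth[off.line_id])
        other = panel.lines[rng.integers(len(panel.lines))]
        lf = lod_score(off, mother, father, freqs, NO_ERROR).lod
        lo = lod_score(off, mother, other, freqs, NO_ERROR).lod
        if math.isinf(lo):
            diffs.append(1.0)
        else:
            diffs.append(1.0 if lf >= lo else -1.0)
    assert np.mean(diffs) > 0.9


# ---------------------------------------------------------------------------
# reciprocal detection


def test_reciprocals_basic_set_algebra():
    report = detect_reciprocals([("A", "B"), ("B", "A"), ("A", "C")])
    assert report.n_selections == 3
    assert report.n_distinct_combinations == 2
    assert report.n_reciprocal_pairs == 1
    assert report.reciprocal_pairs == [("A", "B")]
    assert report.multiplicity[("A", "B")] == 2


def test_reciprocals_none_without_reversals():
    report = detect_reciprocals([("A", "B"), ("A", "C"), ("B", "C")])
    assert report.n_reciprocal_pairs == 0
    assert report.n_distinct_combinations == 3


def test_reciprocals_from_assignments():
    def mk(off, mo, fa):
        return PaternityAssignment(
            offspring_id=off, mother_id=mo, ranked=[], lod=5.0, delta=1.0,
            confidence="strict", assigned_father=fa,
        )

    unassigned = PaternityAssignment(
        offspring_id="u", mother_id="A", ranked=[], lod=-1.0, delta=0.0,
        confidence="unassigned", assigned_father=None,
    )
    report = detect_reciprocals([mk("o1", "A", "B"), mk("o2", "B", "A"), unassigned])
    assert report.n_selections == 2
    assert report.n_reciprocal_pairs == 1
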