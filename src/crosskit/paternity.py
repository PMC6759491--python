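"""Likelihood-ratio paternity assignment with known mothers.

The per-locus likelihood of an offspring genotype given a candidate trio is
blended with a genotyping-error model as a mixture::

    P_obs = (1 - e) * P_mendel + e * P_hwe(offspring genotype)

so an excluded candidate keeps a finite (but heavily penalised) likelihood
when the mistype rate ``e`` is positive.  The LOD of a candidate father is
the natural log of the ratio of this likelihood to the same quantity with
the paternal allele integrated over population frequencies.  Confidence
thresholds for the best-candidate statistic (LOD, or the gap Delta to the
runner-up) are calibrated by Monte-Carlo simulation of trios drawn from the
allele frequencies, mirroring the classical parentage-software workflow.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from .genotypes import AlleleFrequencyTable, Genotype, LineGenotype, MarkerPanel

__all__ = [
    "ErrorModel",
    "CandidateScore",
    "PaternityAssignment",
    "ConfidenceThresholds",
    "ReciprocalReport",
    "transition_prob",
    "lod_score",
    "simulate_confidence_thresholds",
    "assign_paternity",
    "detect_reciprocals",
]


@dataclass(frozen=True)
class ErrorModel:
    """Scoring error model: probability a locus is typed at all, and the
    probability a typed locus genotype is wrong."""

    typed_rate: float = 0.998
    mistype_rate: float = 0.002

    def __post_init__(self) -> None:
        for name in ("typed_rate", "mistype_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


NO_ERROR = ErrorModel(typed_rate=1.0, mistype_rate=0.0)


# ---------------------------------------------------------------------------
# Per-locus likelihoods


def _mendel_p(off: Genotype, mother: Genotype, father: Genotype) -> float:
    """P(offspring genotype | both parental genotypes), error-free."""
    p = 0.0
    for ma in mother:
        for pa in father:
            pair = (ma, pa) if ma <= pa else (pa, ma)
            if pair == off:
                p += 0.25
    return p


def _mother_only_p(off: Genotype, mother: Genotype, freq) -> float:
    """P(offspring genotype | mother), paternal allele ~ population freqs."""
    p = 0.0
    seen = off if off[0] != off[1] else (off[0],)
    for ma in mother:
        for a in seen:
            pair = (ma, a) if ma <= a else (a, ma)
            if pair == off:
                p += 0.5 * freq(a)
    return p


def _hwe_p(geno: Genotype, freq) -> float:
    x, y = geno
    return freq(x) ** 2 if x == y else 2.0 * freq(x) * freq(y)


def transition_prob(
    offspring_geno: Genotype,
    mother_geno: Genotype,
    father_geno: Genotype | None,
    freqs: AlleleFrequencyTable,
    locus: str,
    error: ErrorModel = NO_ERROR,
) -> float:
    """Error-blended probability of the observed offspring genotype at one locus.

    With ``father_geno`` given, the Mendelian trio probability; with it
    ``None``, the paternal allele is integrated over the frequency table.
    """
    freq = lambda a: freqs.get(locus, a)
    if father_geno is None:
        base = _mother_only_p(offspring_geno, mother_geno, freq)
    else:
        base = _mendel_p(offspring_geno, mother_geno, father_geno)
    e = error.mistype_rate
    if e == 0.0:
        return base
    return (1.0 - e) * base + e * _hwe_p(offspring_geno, freq)


@dataclass
class LodResult:
    lod: float
    per_locus: dict[str, float]
    n_typed: int
    n_mismatch: int
    evaluable: bool
    is_self: bool = False


def lod_score(
    offspring: LineGenotype,
    mother: LineGenotype,
    candidate: LineGenotype,
    freqs: AlleleFrequencyTable,
    error: ErrorModel = NO_ERROR,
    min_typed_loci: int | None = None,
) -> LodResult:
    """Total LOD of ``candidate`` as the father of ``offspring``.

    Sums ``ln(P(off|mo,fa) / P(off|mo))`` over loci typed in all three
    individuals; a locus where the trio is Mendelian-impossible counts as a
    mismatch and, with a zero error rate, drives the LOD to ``-inf``.
    Returns ``evaluable=False`` when fewer than ``min_typed_loci`` loci are
    jointly typed (default: every panel locus must be typed).
    """
    loci = [
        l
        for l in freqs.loci
        if offspring.is_typed(l) and mother.is_typed(l) and candidate.is_typed(l)
    ]
    if min_typed_loci is None:
        min_typed_loci = len(freqs.loci)
    per_locus: dict[str, float] = {}
    total = 0.0
    mismatches = 0
    for locus in loci:
        off, mo, fa = offspring.genotype[locus], mother.genotype[locus], candidate.genotype[locus]
        if _mendel_p(off, mo, fa) == 0.0:
            mismatches += 1
        num = transition_prob(off, mo, fa, freqs, locus, error)
        den = transition_prob(off, mo, None, freqs, locus, error)
        ratio = math.log(num / den) if num > 0.0 and den > 0.0 else -math.inf
        per_locus[locus] = ratio
        total += ratio
    is_self = candidate.line_id == mother.line_id
    return LodResult(
        lod=total,
        per_locus=per_locus,
        n_typed=len(loci),
        n_mismatch=mismatches,
        evaluable=len(loci) >= min_typed_loci,
        is_self=is_self,
    )


# ---------------------------------------------------------------------------
# Confidence threshold simulation


@dataclass(frozen=True)
class ConfidenceThresholds:
    """LOD (and Delta) critical values calibrated by simulation."""

    strict_lod: float
    relaxed_lod: float
    strict_delta: float
    relaxed_delta: float
    n_progeny: int
    n_candidates: int
    prop_sampled: float
    error: ErrorModel
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.strict_lod < self.relaxed_lod:
            raise ValueError("strict threshold must be >= relaxed threshold")

    def threshold(self, level: str, statistic: str = "lod") -> float:
        return getattr(self, f"{level}_{'lod' if statistic == 'lod' else 'delta'}")


def _critical_value(stats: np.ndarray, correct: np.ndarray, level: float) -> float:
    """Smallest cut-off such that trials at or above it are ``level`` accurate.

    Scans prefixes of the trials sorted by decreasing statistic and returns
    the statistic at the largest prefix whose running accuracy still meets
    ``level``; ``+inf`` if no prefix qualifies.
    """
    order = np.argsort(-stats, kind="stable")
    sorted_stats = stats[order]
    cum_acc = np.cumsum(correct[order]) / np.arange(1, len(stats) + 1)
    ok = np.flatnonzero(cum_acc >= level)
    if ok.size == 0:
        return math.inf
    return float(sorted_stats[ok[-1]])


def simulate_confidence_thresholds(
    freqs: AlleleFrequencyTable,
    n_candidates: int,
    n_progeny: int = 10_000,
    prop_sampled: float = 1.0,
    error: ErrorModel = ErrorModel(),
    strict_level: float = 0.95,
    relaxed_level: float = 0.80,
    seed: int | None = None,
    min_typed_loci: int | None = None,
) -> ConfidenceThresholds:
    """Monte-Carlo calibration of strict/relaxed assignment thresholds.

    Each trial draws a mother and ``n_candidates`` candidate fathers from the
    allele frequencies (HWE genotypes), picks the true father (present among
    the candidates with probability ``prop_sampled``), produces an offspring,
    applies typing/mistyping noise, and records the best candidate's LOD and
    its Delta over the runner-up together with whether it is the true father.
    The thresholds are the critical values at which the realised accuracy of
    everything above them reaches the requested confidence levels.

    The whole simulation is vectorised over trials and candidates; genotypes
    are carried as indices into each locus's allele table so likelihoods are
    plain array arithmetic.
    """
    if all(len(t) == 1 for t in freqs.freqs.values()):
        raise ValueError("all loci monomorphic: confidence thresholds are undefined")
    rng = np.random.default_rng(seed)
    loci = freqs.loci
    n_loci = len(loci)
    if min_typed_loci is None:
        min_typed_loci = n_loci
    e = error.mistype_rate
    N, C = n_progeny, n_candidates

    typed = rng.random((N, n_loci)) < error.typed_rate
    mistyped = rng.random((N, n_loci)) < e
    true_idx = rng.integers(C, size=N)
    sampled = rng.random(N) < prop_sampled

    lods = np.zeros((N, C))
    with np.errstate(divide="ignore"):
        for li, locus in enumerate(loci):
            p = np.array(list(freqs.freqs[locus].values()))
            p = p / p.sum()
            n_all = len(p)

            def draw(shape):
                return rng.choice(n_all, size=shape, p=p)

            mo = draw((N, 2))
            cand = draw((N, C, 2))
            unsampled_fa = draw((N, 2))
            fa = np.where(sampled[:, None], cand[np.arange(N), true_idx], unsampled_fa)
            ma_allele = mo[np.arange(N), rng.integers(2, size=N)]
            pa_allele = fa[np.arange(N), rng.integers(2, size=N)]
            o1 = np.minimum(ma_allele, pa_allele)
            o2 = np.maximum(ma_allele, pa_allele)
            # mistyped loci are replaced by a fresh HWE genotype
            mt = mistyped[:, li]
            if mt.any():
                wrong = draw((int(mt.sum()), 2))
                o1[mt] = wrong.min(axis=1)
                o2[mt] = wrong.max(axis=1)

            # P(off | mo, cand) for every candidate: mean over the 4 gamete picks
            lo = np.minimum(mo[:, :, None, None], cand[:, None, :, :])
            hi = np.maximum(mo[:, :, None, None], cand[:, None, :, :])
            match = (lo == o1[:, None, None, None]) & (hi == o2[:, None, None, None])
            p_mendel = 0.25 * match.sum(axis=(1, 3))  # (N, C)

            # P(off | mo) with the paternal allele from the population
            hom = o1 == o2
            pm = np.zeros(N)
            for mcol in range(2):
                ma = mo[:, mcol]
                pm += 0.5 * np.where(ma == o1, p[o2], 0.0)
                pm += 0.5 * np.where(~hom & (ma == o2), p[o1], 0.0)
            p_hwe = np.where(hom, p[o1] ** 2, 2.0 * p[o1] * p[o2])

            num = (1.0 - e) * p_mendel + e * p_hwe[:, None]
            den = (1.0 - e) * pm + e * p_hwe
            contrib = np.log(num) - np.log(den)[:, None]
            lods += np.where(typed[:, [li]], contrib, 0.0)

    evaluable = typed.sum(axis=1) >= min_typed_loci
    if not evaluable.any():
        raise ValueError("no evaluable simulated trial (typed loci below minimum)")
    lods = lods[evaluable]
    true_idx = true_idx[evaluable]
    sampled = sampled[evaluable]
    order = np.argsort(-lods, axis=1)
    top = order[:, 0]
    stats = lods[np.arange(len(lods)), top]
    if C > 1:
        deltas = stats - lods[np.arange(len(lods)), order[:, 1]]
    else:
        deltas = np.full(len(lods), math.inf)
    correct = sampled & (top == true_idx)
    strict_lod = _critical_value(stats, correct, strict_level)
    relaxed_lod = _critical_value(stats, correct, relaxed_level)
    strict_delta = _critical_value(deltas, correct, strict_level)
    relaxed_delta = _critical_value(deltas, correct, relaxed_level)
    return ConfidenceThresholds(
        strict_lod=strict_lod,
        relaxed_lod=min(relaxed_lod, strict_lod),
        strict_delta=strict_delta,
        relaxed_delta=min(relaxed_delta, strict_delta),
        n_progeny=n_progeny,
        n_candidates=n_candidates,
        prop_sampled=prop_sampled,
        error=error,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Assignment


@dataclass
class CandidateScore:
    candidate_id: str
    lod: float
    n_typed: int
    n_mismatch: int
    is_self: bool


@dataclass
class PaternityAssignment:
    """Ranked candidate fathers for one offspring with the final call.

    ``assigned_father`` is set only for a confident, genotypically unique
    top candidate; a tie among identical candidates is reported as an
    ``ambiguous_group`` instead (never a confident unique father).
    """

    offspring_id: str
    mother_id: str
    ranked: list[CandidateScore]
    lod: float
    delta: float
    confidence: str  # strict | relaxed | unassigned
    assigned_father: str | None
    ambiguous_group: list[str] = field(default_factory=list)
    maternal_ok: bool = True
    note: str = ""


def _maternal_compatible(offspring: LineGenotype, mother: LineGenotype, loci) -> bool:
    for locus in loci:
        off, mo = offspring.genotype.get(locus), mother.genotype.get(locus)
        if off is None or mo is None:
            continue
        if off[0] not in mo and off[1] not in mo:
            return False
    return True


def assign_paternity(
    offspring: list[LineGenotype],
    candidates: MarkerPanel,
    freqs: AlleleFrequencyTable,
    thresholds: ConfidenceThresholds,
    error: ErrorModel = ErrorModel(),
    min_typed_loci: int | None = None,
    statistic: str = "lod",
    mothers: MarkerPanel | None = None,
) -> list[PaternityAssignment]:
    """Assign the most-likely candidate father to every offspring.

    The top candidate is accepted at strict/relaxed confidence only if its
    gating statistic clears the corresponding threshold and it carries zero
    mismatching loci.  Candidates genotypically identical to the top one are
    grouped and the call is flagged ambiguous.  An offspring whose genotype
    is incompatible with its recorded mother is reported with
    ``maternal_ok=False`` and left unassigned — maternity is a recorded fact
    and is never reassigned.
    """
    if statistic not in ("lod", "delta"):
        raise ValueError(f"unknown statistic {statistic!r}")
    mother_source = mothers if mothers is not None else candidates
    loci = freqs.loci
    if min_typed_loci is None:
        min_typed_loci = len(loci)

    out: list[PaternityAssignment] = []
    for off in offspring:
        if off.maternal_id is None:
            raise ValueError(f"offspring {off.line_id} has no recorded maternal_id")
        mother = mother_source.by_id(off.maternal_id)
        if not _maternal_compatible(off, mother, loci):
            out.append(
                PaternityAssignment(
                    offspring_id=off.line_id,
                    mother_id=mother.line_id,
                    ranked=[],
                    lod=-math.inf,
                    delta=0.0,
                    confidence="unassigned",
                    assigned_father=None,
                    maternal_ok=False,
                    note="maternal discrepancy: offspring incompatible with recorded mother",
                )
            )
            continue

        scored: list[tuple[CandidateScore, LineGenotype]] = []
        for cand in candidates.lines:
            res = lod_score(off, mother, cand, freqs, error, min_typed_loci)
            if not res.evaluable:
                continue
            scored.append(
                (
                    CandidateScore(
                        candidate_id=cand.line_id,
                        lod=res.lod,
                        n_typed=res.n_typed,
                        n_mismatch=res.n_mismatch,
                        is_self=res.is_self,
                    ),
                    cand,
                )
            )
        scored.sort(key=lambda sc: -sc[0].lod)
        ranked = [s for s, _ in scored]
        if not ranked:
            out.append(
                PaternityAssignment(
                    offspring_id=off.line_id,
                    mother_id=mother.line_id,
                    ranked=[],
                    lod=-math.inf,
                    delta=0.0,
                    confidence="unassigned",
                    assigned_father=None,
                    note="no evaluable candidate (typed loci below minimum)",
                )
            )
            continue

        top_score, top_line = scored[0]
        top_key = top_line.multilocus_key(loci)
        group = [
            s.candidate_id
            for s, line in scored
            if abs(s.lod - top_score.lod) <= 1e-9 and line.multilocus_key(loci) == top_key
        ]
        # Delta measured against the best genotypically distinct competitor
        delta = math.inf
        for s, line in scored[1:]:
            if line.multilocus_key(loci) != top_key:
                delta = top_score.lod - s.lod
                break

        stat = top_score.lod if statistic == "lod" else delta
        confidence = "unassigned"
        if top_score.n_mismatch == 0 and math.isfinite(top_score.lod):
            if stat >= thresholds.threshold("strict", statistic):
                confidence = "strict"
            elif stat >= thresholds.threshold("relaxed", statistic):
                confidence = "relaxed"

        ambiguous = len(group) > 1
        out.append(
            PaternityAssignment(
                offspring_id=off.line_id,
                mother_id=mother.line_id,
                ranked=ranked,
                lod=top_score.lod,
                delta=delta,
                confidence=confidence,
                assigned_father=(
                    top_score.candidate_id if (confidence != "unassigned" and not ambiguous) else None
                ),
                ambiguous_group=group if ambiguous else [],
                note="tie among genotypically identical candidates" if ambiguous else "",
            )
        )
    return out


# ---------------------------------------------------------------------------
# Reciprocal / duplicate detection


@dataclass
class ReciprocalReport:
    n_selections: int
    n_distinct_combinations: int
    reciprocal_pairs: list[tuple[str, str]]
    multiplicity: dict[tuple[str, str], int]

    @property
    def n_reciprocal_pairs(self) -> int:
        return len(self.reciprocal_pairs)


def detect_reciprocals(
    assignments: list[PaternityAssignment] | list[tuple[str, str]],
) -> ReciprocalReport:
    """Group selections by unordered parent pair and flag reciprocals.

    Accepts either :class:`PaternityAssignment` records (only those with an
    assigned father contribute) or plain ``(mother_id, father_id)`` tuples.
    A reciprocal pair is an unordered pair observed in both orientations.
    """
    pairs: list[tuple[str, str]] = []
    for item in assignments:
        if isinstance(item, PaternityAssignment):
            if item.assigned_father is None:
                continue
            pairs.append((item.mother_id, item.assigned_father))
        else:
            pairs.append((item[0], item[1]))

    ordered = Counter(pairs)
    unordered: Counter[tuple[str, str]] = Counter()
    orientations: dict[tuple[str, str], set[tuple[str, str]]] = defaultdict(set)
    for (mo, fa), c in ordered.items():
        key = (mo, fa) if mo <= fa else (fa, mo)
        unordered[key] += c
        orientations[key].add((mo, fa))

    reciprocal = sorted(k for k, o in orientations.items() if len(o) > 1)
    return ReciprocalReport(
        n_selections=len(pairs),
        n_distinct_combinations=len(unordered),
        reciprocal_pairs=reciprocal,
        multiplicity=dict(unordered),
    )
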