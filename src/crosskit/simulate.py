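"""End-to-end simulation of the inter-pollination breeding scheme.

Stages: build a homozygous (DH) marker panel, inter-pollinate mothers with a
uniform pollen mixture, add typing noise to offspring genotypes, optionally
phenotype and select elites, then run paternity assignment and compare the
realised per-row paternal diversity with the closed-form occupancy
probability from :mod:`crosskit.design`.

Every stage takes its randomness from seeds spawned deterministically off the
run seed, so stages are individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats as sps

from .design import DesignParams, q_probability
from .genotypes import (
    AlleleFrequencyTable,
    Genotype,
    LineGenotype,
    MarkerPanel,
    allele_frequencies,
)
from .paternity import (
    ErrorModel,
    assign_paternity,
    detect_reciprocals,
    simulate_confidence_thresholds,
)

__all__ = [
    "LocusSpec",
    "SimulationConfig",
    "RecoveryReport",
    "default_loci_spec",
    "simulate_dh_panel",
    "simulate_interpollination",
    "apply_typing_noise",
    "simulate_phenotypes_and_select",
    "distinct_father_fraction",
    "recovery_experiment",
]


@dataclass(frozen=True)
class LocusSpec:
    """One simulated SSR locus: its allele labels (fragment lengths) and
    their sampling probabilities (uniform when omitted)."""

    locus_id: str
    alleles: tuple[int, ...]
    probs: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.alleles) < 1:
            raise ValueError(f"{self.locus_id}: need at least one allele")
        if self.probs is not None:
            if len(self.probs) != len(self.alleles):
                raise ValueError(f"{self.locus_id}: probs/alleles length mismatch")
            if abs(sum(self.probs) - 1.0) > 1e-9:
                raise ValueError(f"{self.locus_id}: probs must sum to 1")

    def prob_array(self) -> np.ndarray:
        if self.probs is None:
            return np.full(len(self.alleles), 1.0 / len(self.alleles))
        p = np.asarray(self.probs, dtype=float)
        return p / p.sum()


def default_loci_spec(n_loci: int = 8, alleles_per_locus=(3, 5, 4, 5, 5, 2, 3, 2)) -> list[LocusSpec]:
    """An 8-locus panel shaped like a typical cabbage SSR set: 29 alleles in
    total, 2-5 per locus, labelled as plausible fragment lengths."""
    if isinstance(alleles_per_locus, int):
        alleles_per_locus = (alleles_per_locus,) * n_loci
    if len(alleles_per_locus) < n_loci:
        raise ValueError("alleles_per_locus shorter than n_loci")
    specs = []
    for i in range(n_loci):
        n_all = alleles_per_locus[i]
        base = 120 + 25 * i
        specs.append(LocusSpec(f"L{i + 1}", tuple(base + 3 * a for a in range(n_all))))
    return specs


def _spawn(seed, n: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]


# ---------------------------------------------------------------------------
# Stage 1: DH panel


def simulate_dh_panel(
    n_lines: int,
    loci_spec: list[LocusSpec],
    seed=None,
    require_distinct: bool = True,
    max_tries: int = 1000,
    rng: np.random.Generator | None = None,
    id_prefix: str = "P",
) -> MarkerPanel:
    """Draw ``n_lines`` fully homozygous lines, one allele per locus.

    With ``require_distinct`` the multilocus genotypes are rejection-resampled
    until unique; fails after ``max_tries`` rounds when the panel cannot be
    distinct (too little allelic diversity)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    loci = [s.locus_id for s in loci_spec]

    def draw_line(i: int) -> LineGenotype:
        geno: dict[str, Genotype | None] = {}
        for spec in loci_spec:
            a = int(rng.choice(np.asarray(spec.alleles), p=spec.prob_array()))
            geno[spec.locus_id] = (a, a)
        return LineGenotype(f"{id_prefix}{i + 1}", geno, role="parent")

    lines = [draw_line(i) for i in range(n_lines)]
    if require_distinct:
        for _ in range(max_tries):
            keys: dict[tuple, int] = {}
            dup_idx = []
            for idx, line in enumerate(lines):
                key = line.multilocus_key(loci)
                if key in keys:
                    dup_idx.append(idx)
                else:
                    keys[key] = idx
            if not dup_idx:
                break
            for idx in dup_idx:
                lines[idx] = draw_line(idx)
        else:
            raise ValueError(
                f"could not draw {n_lines} distinct multilocus genotypes in "
                f"{max_tries} rounds; increase allelic diversity"
            )
    return MarkerPanel(loci=loci, lines=lines)


# ---------------------------------------------------------------------------
# Stage 2: inter-pollination


def simulate_interpollination(
    panel: MarkerPanel,
    k_per_mother: int,
    self_incompatible: bool = False,
    seed=None,
    rng: np.random.Generator | None = None,
) -> tuple[list[LineGenotype], dict[str, str]]:
    """Produce ``k`` offspring per mother with uniformly drawn fathers.

    Fathers are drawn from all lines (the mother included unless
    ``self_incompatible``); each offspring locus gets one random maternal and
    one random paternal allele.  Returns the offspring records and the hidden
    ground-truth map offspring_id -> father_id.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    parents = panel.lines
    n = len(parents)
    loci = panel.loci
    offspring: list[LineGenotype] = []
    truth: dict[str, str] = {}
    for mi, mother in enumerate(parents):
        if self_incompatible and n < 2:
            raise ValueError("self-incompatible pollination needs at least 2 lines")
        fathers = rng.integers(0, n - 1 if self_incompatible else n, size=k_per_mother)
        if self_incompatible:
            fathers = np.where(fathers >= mi, fathers + 1, fathers)
        m_pick = rng.integers(0, 2, size=(k_per_mother, len(loci)))
        p_pick = rng.integers(0, 2, size=(k_per_mother, len(loci)))
        for j in range(k_per_mother):
            father = parents[int(fathers[j])]
            geno: dict[str, Genotype | None] = {}
            for li, locus in enumerate(loci):
                ma = mother.genotype[locus][m_pick[j, li]]
                pa = father.genotype[locus][p_pick[j, li]]
                geno[locus] = (ma, pa) if ma <= pa else (pa, ma)
            oid = f"{mother.line_id}_{j + 1}"
            offspring.append(
                LineGenotype(oid, geno, role="offspring", maternal_id=mother.line_id)
            )
            truth[oid] = father.line_id
    return offspring, truth


def distinct_father_fraction(
    n: int,
    k: int,
    m: int,
    n_mothers: int,
    self_incompatible: bool = False,
    seed=None,
    rng: np.random.Generator | None = None,
) -> tuple[float, int]:
    """Empirical fraction of maternal rows with >= ``m`` distinct non-maternal
    fathers, over ``n_mothers`` independent rows of ``k`` uniform draws.

    This is the father-draw core of :func:`simulate_interpollination` without
    genotype materialisation, so large replicate counts stay cheap.  Returns
    ``(fraction, successes)``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    successes = 0
    for _ in range(n_mothers):
        # by symmetry the focal mother is line 0
        if self_incompatible:
            draws = rng.integers(1, n, size=k)
        else:
            draws = rng.integers(0, n, size=k)
        distinct = np.unique(draws)
        successes += int((distinct != 0).sum() >= m)
    return successes / n_mothers if n_mothers else 0.0, successes


# ---------------------------------------------------------------------------
# Stage 3: typing noise


def apply_typing_noise(
    offspring: list[LineGenotype],
    typed_rate: float,
    mistype_rate: float,
    freqs: AlleleFrequencyTable,
    seed=None,
    rng: np.random.Generator | None = None,
) -> list[LineGenotype]:
    """Independently drop each offspring locus with probability
    ``1 - typed_rate`` and replace each surviving one with a random HWE
    genotype with probability ``mistype_rate``."""
    err = ErrorModel(typed_rate=typed_rate, mistype_rate=mistype_rate)
    if rng is None:
        rng = np.random.default_rng(seed)
    if err.typed_rate == 1.0 and err.mistype_rate == 0.0:
        return [
            LineGenotype(o.line_id, dict(o.genotype), role=o.role, maternal_id=o.maternal_id)
            for o in offspring
        ]
    tables = {
        l: (np.array(list(freqs.freqs[l])), np.array(list(freqs.freqs[l].values())))
        for l in freqs.loci
    }
    for l, (a, p) in tables.items():
        tables[l] = (a, p / p.sum())
    noisy: list[LineGenotype] = []
    for o in offspring:
        geno: dict[str, Genotype | None] = {}
        for locus, pair in o.genotype.items():
            if pair is None:
                geno[locus] = None
                continue
            if rng.random() >= err.typed_rate:
                geno[locus] = None
            elif rng.random() < err.mistype_rate:
                alleles, probs = tables[locus]
                a, b = rng.choice(alleles, size=2, p=probs)
                geno[locus] = (int(a), int(b)) if a <= b else (int(b), int(a))
            else:
                geno[locus] = pair
        noisy.append(LineGenotype(o.line_id, geno, role=o.role, maternal_id=o.maternal_id))
    return noisy


# ---------------------------------------------------------------------------
# Stage 4: phenotypes and selection


def simulate_phenotypes_and_select(
    offspring: list[LineGenotype],
    truth: dict[str, str],
    selection_fraction: float,
    line_effect_sd: float = 1.0,
    pair_deviation_sd: float = 0.0,
    noise_sd: float = 0.0,
    seed=None,
    rng: np.random.Generator | None = None,
) -> list[tuple[LineGenotype, float]]:
    """Score each offspring as mother effect + father effect + pair deviation
    + noise (an additive GCA model with an SCA-like term) and keep the top
    ``selection_fraction`` across the whole field."""
    if not 0.0 < selection_fraction <= 1.0:
        raise ValueError(f"selection_fraction must be in (0, 1], got {selection_fraction}")
    if rng is None:
        rng = np.random.default_rng(seed)
    parent_ids = sorted({o.maternal_id for o in offspring} | set(truth.values()))
    effects = {pid: rng.normal(0.0, line_effect_sd) for pid in parent_ids}
    pair_dev: dict[tuple[str, str], float] = {}
    scored: list[tuple[LineGenotype, float]] = []
    for o in offspring:
        mo, fa = o.maternal_id, truth[o.line_id]
        key = (mo, fa) if mo <= fa else (fa, mo)
        if key not in pair_dev:
            pair_dev[key] = rng.normal(0.0, pair_deviation_sd) if pair_deviation_sd else 0.0
        pheno = effects[mo] + effects[fa] + pair_dev[key]
        if noise_sd:
            pheno += rng.normal(0.0, noise_sd)
        scored.append((o, float(pheno)))
    n_keep = max(1, int(round(selection_fraction * len(scored))))
    scored.sort(key=lambda t: -t[1])
    return scored[:n_keep]


# ---------------------------------------------------------------------------
# Stage 5: recovery experiment


@dataclass
class SimulationConfig:
    """Parameters of a full pipeline run."""

    n_lines: int = 31
    k_per_mother: int = 120
    m_required: int = 30
    loci_spec: list[LocusSpec] = field(default_factory=default_loci_spec)
    self_incompatible: bool = False
    typed_rate: float = 1.0
    mistype_rate: float = 0.0
    selection_fraction: float | None = None
    line_effect_sd: float = 1.0
    pair_deviation_sd: float = 0.25
    noise_sd: float = 0.5
    q_replicate_mothers: int = 2000
    assign_sample: int = 500
    threshold_progeny: int = 2000
    strict_level: float = 0.95
    relaxed_level: float = 0.80
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_lines < 2:
            raise ValueError("n_lines must be >= 2")
        if self.k_per_mother < 0:
            raise ValueError("k_per_mother must be >= 0")
        for name in ("typed_rate", "mistype_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class RecoveryReport:
    """Outcome of the pipeline validated against the closed-form model."""

    config_seed: int | None
    n_lines: int
    k_per_mother: int
    m_required: int
    empirical_fraction: float
    n_replicate_mothers: int
    predicted_q: float
    ci_low_count: int
    ci_high_count: int
    successes: int
    within_ci: bool
    n_assigned_sample: int
    accuracy: float
    fraction_strict: float
    fraction_ambiguous: float
    fraction_unassigned: float
    n_selected: int
    n_distinct_combinations: int
    n_reciprocal_pairs: int

    def to_dict(self) -> dict:
        return asdict(self)


def recovery_experiment(config: SimulationConfig) -> RecoveryReport:
    """Run the full pipeline and validate it against the closed-form model.

    The per-row paternal-diversity fraction is measured over
    ``q_replicate_mothers`` replicate rows and checked against ``Q(n, k, m)``
    with an exact (Clopper-Pearson style) central 99% binomial acceptance
    region.  Paternity accuracy is measured on a subsample of offspring using
    thresholds calibrated on the simulated panel; reciprocal statistics come
    from the phenotypic selection when ``selection_fraction`` is set,
    otherwise from the assignment subsample.
    """
    rngs = _spawn(config.seed, 6)
    r_panel, r_q, r_poll, r_noise, r_pheno, r_thresh = rngs

    panel = simulate_dh_panel(config.n_lines, config.loci_spec, rng=r_panel)
    freqs = allele_frequencies(panel)

    # theory check: empirical >= m distinct fathers per replicate row
    frac, successes = distinct_father_fraction(
        config.n_lines,
        config.k_per_mother,
        config.m_required,
        config.q_replicate_mothers,
        self_incompatible=False,  # the closed-form model includes self-draws
        rng=r_q,
    )
    q = q_probability(DesignParams(config.n_lines, config.k_per_mother, config.m_required))
    p = float(q.exact)
    n_rep = config.q_replicate_mothers
    lo = int(sps.binom.ppf(0.005, n_rep, p)) if p > 0 else 0
    hi = int(sps.binom.ppf(0.995, n_rep, p)) if p < 1 else n_rep
    within = lo <= successes <= hi

    # genotype pipeline on a workable family size
    offspring, truth = simulate_interpollination(
        panel,
        config.k_per_mother,
        self_incompatible=config.self_incompatible,
        rng=r_poll,
    )
    noisy = apply_typing_noise(
        offspring, config.typed_rate, config.mistype_rate, freqs, rng=r_noise
    )

    if config.selection_fraction is not None:
        selected = simulate_phenotypes_and_select(
            noisy,
            truth,
            config.selection_fraction,
            line_effect_sd=config.line_effect_sd,
            pair_deviation_sd=config.pair_deviation_sd,
            noise_sd=config.noise_sd,
            rng=r_pheno,
        )
        to_assign = [o for o, _ in selected]
    else:
        selected = []
        to_assign = noisy
    if config.assign_sample and len(to_assign) > config.assign_sample:
        idx = r_pheno.choice(len(to_assign), size=config.assign_sample, replace=False)
        to_assign = [to_assign[i] for i in sorted(idx)]

    error = ErrorModel(typed_rate=config.typed_rate, mistype_rate=config.mistype_rate)
    thr_seed = int(r_thresh.integers(2**31 - 1))
    thresholds = simulate_confidence_thresholds(
        freqs,
        n_candidates=config.n_lines,
        n_progeny=config.threshold_progeny,
        prop_sampled=1.0,
        error=error,
        strict_level=config.strict_level,
        relaxed_level=config.relaxed_level,
        seed=thr_seed,
    )
    assignments = assign_paternity(
        to_assign, panel, freqs, thresholds, error=error
    )

    n_eval = len(assignments)
    correct = sum(
        1 for a in assignments if a.assigned_father is not None and a.assigned_father == truth[a.offspring_id]
    )
    ambiguous = sum(1 for a in assignments if a.ambiguous_group)
    unassigned = sum(
        1 for a in assignments if a.assigned_father is None and not a.ambiguous_group
    )
    strict = sum(1 for a in assignments if a.confidence == "strict")

    rec = detect_reciprocals(
        [(a.mother_id, a.assigned_father) for a in assignments if a.assigned_father]
    )
    return RecoveryReport(
        config_seed=config.seed,
        n_lines=config.n_lines,
        k_per_mother=config.k_per_mother,
        m_required=config.m_required,
        empirical_fraction=frac,
        n_replicate_mothers=n_rep,
        predicted_q=p,
        ci_low_count=lo,
        ci_high_count=hi,
        successes=successes,
        within_ci=within,
        n_assigned_sample=n_eval,
        accuracy=correct / n_eval if n_eval else 0.0,
        fraction_strict=strict / n_eval if n_eval else 0.0,
        fraction_ambiguous=ambiguous / n_eval if n_eval else 0.0,
        fraction_unassigned=unassigned / n_eval if n_eval else 0.0,
        n_selected=len(selected),
        n_distinct_combinations=rec.n_distinct_combinations,
        n_reciprocal_pairs=rec.n_reciprocal_pairs,
    )
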