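"""Multilocus SSR genotype tables, I/O and marker-informativeness statistics.

A genotype is a pair of integer allele labels (fragment lengths in bp) per
locus; the pair is unordered and stored sorted.  Parent lines from a doubled
haploid programme are homozygous at every locus.  The CSV dialect is
``line_id, role, maternal_id`` followed by two columns per locus,
``<locus>.a1`` / ``<locus>.a2``; missing data is coded 0 (configurable).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "LineGenotype",
    "MarkerPanel",
    "AlleleFrequencyTable",
    "LocusDiversity",
    "IdentityGroups",
    "read_genotypes",
    "write_genotypes",
    "allele_frequencies",
    "diversity_stats",
    "find_identical_lines",
]

MISSING = 0

Genotype = tuple[int, int]


class GenotypeError(ValueError):
    """Malformed genotype data (parse or validation failure)."""


@dataclass
class LineGenotype:
    """One named line (parent or offspring) typed at a set of loci.

    ``genotype`` maps locus id to a sorted allele pair, or ``None`` for a
    missing (untyped) locus.
    """

    line_id: str
    genotype: dict[str, Genotype | None]
    role: str = "parent"
    maternal_id: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ("parent", "offspring"):
            raise GenotypeError(f"{self.line_id}: unknown role {self.role!r}")
        norm: dict[str, Genotype | None] = {}
        for locus, pair in self.genotype.items():
            if pair is None:
                norm[locus] = None
                continue
            a, b = pair
            if a == MISSING or b == MISSING:
                if a != b:
                    raise GenotypeError(
                        f"{self.line_id}/{locus}: half-typed locus {pair}; a locus "
                        "is either fully typed or missing"
                    )
                norm[locus] = None
                continue
            norm[locus] = (a, b) if a <= b else (b, a)
        self.genotype = norm

    def typed_loci(self) -> list[str]:
        return [l for l, g in self.genotype.items() if g is not None]

    def is_typed(self, locus: str) -> bool:
        return self.genotype.get(locus) is not None

    def is_homozygous(self) -> bool:
        """True when every typed locus carries two identical alleles (DH)."""
        return all(g[0] == g[1] for g in self.genotype.values() if g is not None)

    def multilocus_key(self, loci: list[str]) -> tuple:
        return tuple(self.genotype.get(l) for l in loci)


@dataclass
class MarkerPanel:
    """An ordered marker panel and the lines typed on it."""

    loci: list[str]
    lines: list[LineGenotype]
    locus_metadata: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for line in self.lines:
            if line.line_id in seen:
                raise GenotypeError(f"duplicate line_id {line.line_id!r}")
            seen.add(line.line_id)
            extra = set(line.genotype) - set(self.loci)
            if extra:
                raise GenotypeError(
                    f"{line.line_id}: genotype references undeclared loci {sorted(extra)}"
                )

    def __len__(self) -> int:
        return len(self.lines)

    def by_id(self, line_id: str) -> LineGenotype:
        for line in self.lines:
            if line.line_id == line_id:
                return line
        raise KeyError(line_id)

    def subset(self, roles: set[str]) -> list[LineGenotype]:
        return [l for l in self.lines if l.role in roles]


@dataclass
class AlleleFrequencyTable:
    """Per-locus allele frequencies with the size of the base population.

    ``floor`` is the frequency assigned to an allele never seen in the base
    population (1 / (2N + 1)); it keeps likelihoods finite while penalising
    alleles that should not be there.
    """

    freqs: dict[str, dict[int, float]]
    n_individuals: int

    def __post_init__(self) -> None:
        for locus, table in self.freqs.items():
            total = sum(table.values())
            if abs(total - 1.0) > 1e-12:
                raise GenotypeError(f"{locus}: frequencies sum to {total}, not 1")
            if any(f <= 0 for f in table.values()):
                raise GenotypeError(f"{locus}: zero/negative allele frequency")

    @property
    def loci(self) -> list[str]:
        return list(self.freqs)

    @property
    def floor(self) -> float:
        return 1.0 / (2 * self.n_individuals + 1)

    def get(self, locus: str, allele: int) -> float:
        return self.freqs[locus].get(allele, self.floor)


@dataclass(frozen=True)
class LocusDiversity:
    locus_id: str
    n_alleles: int
    Ho: float
    He: float
    PIC: float
    NE_1P: float


# ---------------------------------------------------------------------------
# I/O

_FIXED_COLS = ["line_id", "role", "maternal_id"]


def read_genotypes(source, missing: int = MISSING) -> MarkerPanel:
    """Parse the genotype CSV dialect into a validated :class:`MarkerPanel`."""
    frame = pd.read_csv(source, dtype=str, keep_default_na=False)
    cols = list(frame.columns)
    if cols[: len(_FIXED_COLS)] != _FIXED_COLS:
        raise GenotypeError(
            f"expected leading columns {_FIXED_COLS}, got {cols[:len(_FIXED_COLS)]}"
        )
    allele_cols = cols[len(_FIXED_COLS) :]
    if len(allele_cols) % 2 != 0:
        raise GenotypeError(f"odd number of allele columns: {allele_cols}")
    loci: list[str] = []
    for i in range(0, len(allele_cols), 2):
        c1, c2 = allele_cols[i], allele_cols[i + 1]
        if not (c1.endswith(".a1") and c2.endswith(".a2") and c1[:-3] == c2[:-3]):
            raise GenotypeError(f"allele columns must pair as <locus>.a1/<locus>.a2: {c1}, {c2}")
        loci.append(c1[:-3])

    lines: list[LineGenotype] = []
    for row_no, row in enumerate(frame.itertuples(index=False), start=2):
        rec = dict(zip(cols, row))
        genotype: dict[str, Genotype | None] = {}
        for locus in loci:
            raw1, raw2 = rec[f"{locus}.a1"].strip(), rec[f"{locus}.a2"].strip()
            try:
                a1 = missing if raw1 == "" else int(raw1)
                a2 = missing if raw2 == "" else int(raw2)
            except ValueError as exc:
                raise GenotypeError(
                    f"row {row_no}, locus {locus}: non-integer allele label "
                    f"({raw1!r}, {raw2!r})"
                ) from exc
            if a1 == missing or a2 == missing:
                if (a1 == missing) != (a2 == missing):
                    raise GenotypeError(
                        f"row {row_no}, locus {locus}: half-typed locus ({raw1!r}, {raw2!r})"
                    )
                genotype[locus] = None
            else:
                genotype[locus] = (a1, a2)
        lines.append(
            LineGenotype(
                line_id=rec["line_id"],
                genotype=genotype,
                role=rec["role"] or "parent",
                maternal_id=rec["maternal_id"] or None,
            )
        )
    return MarkerPanel(loci=loci, lines=lines)


def write_genotypes(panel: MarkerPanel, sink, missing: int = MISSING) -> None:
    """Write a panel in the CSV dialect; round-trips with :func:`read_genotypes`."""
    rows = []
    for line in panel.lines:
        rec: dict[str, object] = {
            "line_id": line.line_id,
            "role": line.role,
            "maternal_id": line.maternal_id or "",
        }
        for locus in panel.loci:
            pair = line.genotype.get(locus)
            if pair is None:
                rec[f"{locus}.a1"] = missing
                rec[f"{locus}.a2"] = missing
            else:
                rec[f"{locus}.a1"], rec[f"{locus}.a2"] = pair
        rows.append(rec)
    columns = _FIXED_COLS + [f"{l}.{a}" for l in panel.loci for a in ("a1", "a2")]
    pd.DataFrame(rows, columns=columns).to_csv(sink, index=False)


# ---------------------------------------------------------------------------
# Statistics


def allele_frequencies(
    panel: MarkerPanel, from_roles: set[str] = frozenset({"parent"})
) -> AlleleFrequencyTable:
    """Allele frequencies per locus from typed allele copies of the chosen roles."""
    base = panel.subset(set(from_roles))
    freqs: dict[str, dict[int, float]] = {}
    for locus in panel.loci:
        counts: Counter[int] = Counter()
        for line in base:
            pair = line.genotype.get(locus)
            if pair is not None:
                counts[pair[0]] += 1
                counts[pair[1]] += 1
        total = sum(counts.values())
        if total == 0:
            raise GenotypeError(f"locus {locus}: no typed genotypes in roles {sorted(from_roles)}")
        freqs[locus] = {a: c / total for a, c in sorted(counts.items())}
    return AlleleFrequencyTable(freqs=freqs, n_individuals=len(base))


def _power_sums(p: list[float], upto: int = 5) -> list[float]:
    return [sum(x**k for x in p) for k in range(upto + 1)]


def diversity_stats(
    panel: MarkerPanel, freqs: AlleleFrequencyTable, roles: set[str] = frozenset({"parent"})
) -> list[LocusDiversity]:
    """Per-locus Ho, Nei He, PIC and one-parent non-exclusion probability.

    NE_1P follows the Jamieson & Taylor power-sum expression for a codominant
    locus when one parent's genotype is known.
    """
    out = []
    lines = panel.subset(set(roles))
    for locus in panel.loci:
        p = list(freqs.freqs[locus].values())
        a = _power_sums(p)
        he = 1.0 - a[2]
        pic = he - sum(
            2 * p[i] ** 2 * p[j] ** 2 for i in range(len(p)) for j in range(i + 1, len(p))
        )
        # exclusion power with one known parent; 1 - P_excl
        ne_1p = 2 * a[2] - a[3] - 2 * a[4] + 3 * a[5] + 2 * a[2] ** 2 - 3 * a[2] * a[3]
        typed = [l.genotype.get(locus) for l in lines if l.is_typed(locus)]
        ho = (
            sum(1 for g in typed if g[0] != g[1]) / len(typed) if typed else 0.0
        )
        out.append(
            LocusDiversity(
                locus_id=locus,
                n_alleles=len(p),
                Ho=ho,
                He=he,
                PIC=pic,
                NE_1P=min(1.0, max(0.0, ne_1p)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Identity detection


@dataclass
class IdentityGroups:
    """Partition of line ids by multilocus genotype.

    ``groups`` lists fully-typed identity classes (size > 1 means paternity
    is non-unique within the class).  ``potential`` maps each incompletely
    typed line to the groups it cannot be distinguished from on its typed
    loci.
    """

    groups: list[list[str]]
    potential: dict[str, list[str]] = field(default_factory=dict)

    def ambiguous(self) -> list[list[str]]:
        return [g for g in self.groups if len(g) > 1]


def find_identical_lines(panel: MarkerPanel, roles: set[str] = frozenset({"parent"})) -> IdentityGroups:
    """Group lines by identical multilocus genotype.

    Lines typed at all loci are grouped exactly; a line with missing loci is
    compared on its typed loci only and reported as *potentially* identical
    to any compatible line.
    """
    lines = panel.subset(set(roles))
    full = [l for l in lines if len(l.typed_loci()) == len(panel.loci)]
    partial = [l for l in lines if len(l.typed_loci()) < len(panel.loci)]

    by_key: dict[tuple, list[str]] = defaultdict(list)
    for line in full:
        by_key[line.multilocus_key(panel.loci)].append(line.line_id)
    groups = sorted(by_key.values(), key=lambda g: g[0])

    potential: dict[str, list[str]] = {}
    for line in partial:
        compatible = []
        for other in full:
            if all(
                line.genotype[l] == other.genotype[l]
                for l in panel.loci
                if line.is_typed(l)
            ):
                compatible.append(other.line_id)
        if compatible:
            potential[line.line_id] = compatible
    return IdentityGroups(groups=groups, potential=potential)
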