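"""Exact family-size planning for random inter-pollination designs.

Given ``n`` inbred lines whose pollen is mixed uniformly, the chance that a
fixed maternal row of ``k`` offspring contains at least ``m`` of the other
``n - 1`` lines as fathers is an occupancy (surjection-counting) probability::

    Q(n, k, m) = n**-k * sum_{j=m}^{n-1} C(n-1, j) * j! * S(k+1, j+1)

where ``S`` is the Stirling number of the second kind.  Everything here is
computed with exact integers and rationals; floating point appears only when a
value is rendered for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import product
from math import comb, factorial

__all__ = [
    "DesignParams",
    "DesignProbability",
    "StirlingCache",
    "stirling2",
    "count_strings_exactly_j",
    "q_probability",
    "min_offspring",
    "probability_table",
    "brute_force_q",
    "cross_count",
]

#: guard for the brute-force enumerator (n**k strings)
BRUTE_FORCE_LIMIT = 10**7


@dataclass(frozen=True)
class DesignParams:
    """Planning parameters: ``n`` lines, ``k`` offspring per maternal row,
    ``m`` required distinct paternal lines (out of the ``n - 1`` non-maternal
    lines)."""

    n: int
    k: int
    m: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")
        if self.k < 0:
            raise ValueError(f"k must be >= 0, got {self.k}")
        if not 0 <= self.m <= self.n - 1:
            raise ValueError(f"m must be in [0, n-1] = [0, {self.n - 1}], got {self.m}")


@dataclass(frozen=True)
class DesignProbability:
    """An exact probability plus its decimal rendering.

    ``exact`` is a rational in [0, 1]; ``rendered`` applies round-half-up at
    ``decimals`` places, so the displayed value is always within half an ulp
    of the exact one.
    """

    exact: Fraction
    decimals: int = 3

    def __post_init__(self) -> None:
        if not 0 <= self.exact <= 1:
            raise ValueError(f"probability out of [0, 1]: {self.exact}")
        if self.decimals < 0:
            raise ValueError("decimals must be >= 0")

    @property
    def rendered(self) -> str:
        return _render_round_half_up(self.exact, self.decimals)

    @property
    def rounded(self) -> float:
        return float(self.rendered)

    def __float__(self) -> float:
        return float(self.exact)

    def __str__(self) -> str:
        return self.rendered


def _render_round_half_up(value: Fraction, decimals: int) -> str:
    """Render an exact non-negative rational with round-half-up."""
    num, den = value.numerator, value.denominator
    scaled = num * 10**decimals
    q = (2 * scaled + den) // (2 * den)  # floor(scaled/den + 1/2)
    if decimals == 0:
        return str(q)
    s = str(q).rjust(decimals + 1, "0")
    return f"{s[:-decimals]}.{s[-decimals:]}"


class StirlingCache:
    """Lazily grown triangular table of Stirling numbers of the second kind.

    Built by the recurrence ``S(k, j) = j*S(k-1, j) + S(k-1, j-1)`` on exact
    integers.  An optional ``max_j`` caps the column range so that tables with
    very large ``k`` (hundreds of rows of multi-thousand-digit integers) only
    hold the columns actually needed.
    """

    def __init__(self, max_j: int | None = None):
        if max_j is not None and max_j < 0:
            raise ValueError("max_j must be >= 0")
        self._max_j = max_j
        self._rows: list[list[int]] = [[1]]  # S(0, 0) = 1

    @property
    def max_row(self) -> int:
        return len(self._rows) - 1

    def value(self, k: int, j: int) -> int:
        if k < 0 or j < 0:
            raise ValueError(f"Stirling arguments must be non-negative, got ({k}, {j})")
        if j > k:
            return 0
        if self._max_j is not None and j > self._max_j:
            raise ValueError(f"column {j} exceeds cache cap max_j={self._max_j}")
        self._extend(k)
        row = self._rows[k]
        return row[j] if j < len(row) else 0

    def _extend(self, k: int) -> None:
        while len(self._rows) <= k:
            prev = self._rows[-1]
            r = len(self._rows)
            width = r + 1 if self._max_j is None else min(r, self._max_j) + 1
            row = [0] * width
            for j in range(1, width):
                s = prev[j - 1] if j - 1 < len(prev) else 0
                if j < len(prev):
                    s += j * prev[j]
                row[j] = s
            self._rows.append(row)


_GLOBAL_CACHE = StirlingCache()


def stirling2(k: int, j: int) -> int:
    """Number of partitions of a ``k``-element set into ``j`` non-empty blocks."""
    return _GLOBAL_CACHE.value(k, j)


def count_strings_exactly_j(n: int, k: int, j: int, cache: StirlingCache | None = None) -> int:
    """Count the strings of length ``k`` over an ``n``-letter alphabet in which
    exactly ``j`` letters other than a fixed letter appear.

    Equals ``C(n-1, j) * j! * S(k+1, j+1)``: the fixed letter may or may not
    occur, which is what folds the two surjection counts into a single
    Stirling term one row down.
    """
    DesignParams(n, k, min(j, n - 1) if j >= 0 else 0)  # validate n, k
    if not 0 <= j <= n - 1:
        raise ValueError(f"j must be in [0, n-1] = [0, {n - 1}], got {j}")
    s = cache.value(k + 1, j + 1) if cache is not None else stirling2(k + 1, j + 1)
    return comb(n - 1, j) * factorial(j) * s


def q_probability(
    params: DesignParams | tuple[int, int, int],
    decimals: int = 3,
    cache: StirlingCache | None = None,
) -> DesignProbability:
    """Exact probability that at least ``m`` distinct non-maternal lines father
    at least one of the ``k`` offspring of a fixed maternal row."""
    if not isinstance(params, DesignParams):
        params = DesignParams(*params)
    n, k, m = params.n, params.k, params.m
    if cache is None:
        cache = StirlingCache(max_j=n)
    total = 0
    for j in range(m, n):
        total += comb(n - 1, j) * factorial(j) * cache.value(k + 1, j + 1)
    return DesignProbability(Fraction(total, n**k), decimals)


def min_offspring(n: int, m: int, p: float | Fraction) -> int:
    """Smallest ``k`` with ``Q(n, k, m) >= p``.

    Exponential bracketing followed by bisection on the exact rational value;
    the search is valid because Q is non-decreasing in ``k``.
    """
    DesignParams(n, 0, m)
    p = Fraction(p)
    if not 0 < p < 1:
        raise ValueError(f"p must be in (0, 1), got {p}")
    cache = StirlingCache(max_j=n)

    def q(k: int) -> Fraction:
        return q_probability(DesignParams(n, k, m), cache=cache).exact

    if q(0) >= p:  # m == 0
        return 0
    hi = max(m, 1)
    while q(hi) < p:
        hi *= 2
    lo = hi // 2  # q(lo) < p or lo bracket start
    while lo + 1 < hi:
        mid = (lo + hi) // 2
        if q(mid) >= p:
            hi = mid
        else:
            lo = mid
    return hi


def probability_table(
    n: int,
    k_values: list[int],
    m_values: list[int],
    decimals: int = 3,
):
    """Grid of rendered probabilities, rows = ``k``, columns = ``m``.

    Returns a pandas DataFrame of decimal strings (exact round-half-up
    rendering), indexed by ``k`` with columns labelled ``Q(n,k,m)``.
    """
    import pandas as pd

    cache = StirlingCache(max_j=n)
    data = {}
    for m in m_values:
        col = []
        for k in k_values:
            col.append(q_probability(DesignParams(n, k, m), decimals, cache).rendered)
        data[f"Q({n},k,{m})"] = col
    frame = pd.DataFrame(data, index=pd.Index(k_values, name="k"))
    return frame


def brute_force_q(params: DesignParams | tuple[int, int, int]) -> Fraction:
    """Verification oracle: enumerate all ``n**k`` pollination strings and
    count those containing at least ``m`` non-maternal lines.  Guarded to
    ``n**k <= 10**7``."""
    if not isinstance(params, DesignParams):
        params = DesignParams(*params)
    n, k, m = params.n, params.k, params.m
    total = n**k
    if total > BRUTE_FORCE_LIMIT:
        raise ValueError(f"n**k = {total} exceeds brute-force guard {BRUTE_FORCE_LIMIT}")
    count = 0
    for s in product(range(n), repeat=k):
        others = set(s)
        others.discard(0)  # letter 0 plays the maternal line
        if len(others) >= m:
            count += 1
    return Fraction(count, total)


def cross_count(n: int) -> int:
    """Number of pairwise crosses among ``n`` lines without reciprocals."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return n * (n - 1) // 2
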