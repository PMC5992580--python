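"""Exact combinatorial statistics shared by every analysis stage.

The cohorts this package targets are tiny (tens of families, a few hundred
reference individuals), so every test is computed exactly: hypergeometric
probabilities are evaluated with arbitrary-precision integer binomial
coefficients, never a normal approximation. The one-tailed Fisher exact
test is the upper hypergeometric tail, oriented as "cases enriched for
exposure"; callers orient the table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

__all__ = [
    "ContingencyTable2x2",
    "hypergeom_pmf",
    "hypergeom_sf_ge",
    "fisher_one_tailed_greater",
    "bonferroni_adjust",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for a 2x2 case/control exposure table.

    a: exposed cases, b: unexposed cases, c: exposed controls,
    d: unexposed controls.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(not isinstance(x, (int,)) or isinstance(x, bool) for x in cells):
            raise ValueError(f"table cells must be integers, got {cells!r}")
        if any(x < 0 for x in cells):
            raise ValueError(f"table cells must be non-negative, got {cells!r}")
        if sum(cells) == 0:
            raise ValueError("contingency table is empty (all cells zero)")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def _check_params(N: int, K: int, n: int) -> None:
    if not (0 <= K <= N):
        raise ValueError(f"require 0 <= K <= N, got K={K}, N={N}")
    if not (0 <= n <= N):
        raise ValueError(f"require 0 <= n <= N, got n={n}, N={N}")


def _pmf_fraction(k: int, N: int, K: int, n: int) -> Fraction:
    return Fraction(math.comb(K, k) * math.comb(N - K, n - k), math.comb(N, n))


def hypergeom_pmf(k: int, N: int, K: int, n: int) -> float:
    """P(X = k) when drawing n without replacement from N with K successes.

    Out-of-support k yields 0.0; invalid parameter orderings raise
    ``ValueError``.
    """
    _check_params(N, K, n)
    if k < max(0, n + K - N) or k > min(n, K):
        return 0.0
    return float(_pmf_fraction(k, N, K, n))


def hypergeom_sf_ge(k: int, N: int, K: int, n: int) -> float:
    """Upper tail P(X >= k) of the hypergeometric distribution.

    Computed as an exact rational sum over the support, so the result is
    never 0 for a feasible tail; should the exact value underflow float
    conversion, a log-gamma evaluation of the leading term is returned
    instead of 0.
    """
    _check_params(N, K, n)
    lo = max(0, n + K - N)
    hi = min(n, K)
    if k <= lo:
        return 1.0
    if k > hi:
        return 0.0
    denom = math.comb(N, n)
    num = sum(math.comb(K, j) * math.comb(N - K, n - j) for j in range(k, hi + 1))
    p = num / Fraction(denom)
    out = float(p)
    if out == 0.0:  # exact tail smaller than smallest subnormal float
        out = math.exp(
            math.lgamma(K + 1) - math.lgamma(k + 1) - math.lgamma(K - k + 1)
            + math.lgamma(N - K + 1) - math.lgamma(n - k + 1)
            - math.lgamma(N - K - n + k + 1)
            + math.lgamma(n + 1) + math.lgamma(N - n + 1) - math.lgamma(N + 1)
        )
    return min(out, 1.0)


def fisher_one_tailed_greater(table: ContingencyTable2x2) -> float:
    """One-tailed Fisher exact p, alternative: cases enriched for exposure.

    Equals the upper hypergeometric tail P(X >= a) with population
    N = a+b+c+d, K = a+c exposed in total, n = a+b cases drawn.
    """
    t = table
    return hypergeom_sf_ge(t.a, N=t.total, K=t.a + t.c, n=t.a + t.b)


def bonferroni_adjust(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni family-wise adjustment: p -> min(1, p * m), order kept.

    ``m`` defaults to the list length; it may be passed explicitly when
    the family of tests is larger than the p-values at hand.
    """
    ps = list(p_values)
    if not ps:
        raise ValueError("bonferroni_adjust requires a non-empty list")
    if any(not (0.0 < p <= 1.0) for p in ps):
        raise ValueError("p-values must lie in (0, 1]")
    mm = len(ps) if m is None else m
    if mm < len(ps):
        raise ValueError(f"m={mm} smaller than number of tests {len(ps)}")
    return [min(1.0, p * mm) for p in ps]
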