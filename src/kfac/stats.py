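"""Shared exact statistics.

The two-sided Fisher's exact test used by the expression-bias and
MAE-enrichment analyses.  The p-value is computed by the point-probability
method — the sum of hypergeometric probabilities of all tables (with the
observed margins) no more probable than the observed one — using exact integer
hypergeometric weights, so tie decisions are exact rather than subject to
floating-point rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class BiasTable:
    """A 2x2 expression-bias contingency summary.

    ``a`` of ``A`` focal-class opportunities were expression events; ``b`` of
    ``B`` in the comparison class.  The Fisher test is run on the table
    ((a, A-a), (b, B-b)).  ``odds_ratio`` is the sample odds ratio with
    ``inf`` as the degenerate-table sentinel.
    """

    a: int
    A: int
    b: int
    B: int
    odds_ratio: float
    p_value: float

    @property
    def focal_fraction(self) -> float:
        return self.a / self.A

    @property
    def comparison_fraction(self) -> float:
        return self.b / self.B


def _hypergeom_weights(N: int, K: int, n: int) -> tuple[int, list[int]]:
    """Integer weights C(K,k)*C(N-K,n-k) for k in [kmin, kmax]; returns (kmin, weights)."""
    kmin = max(0, n - (N - K))
    kmax = min(K, n)
    w = math.comb(K, kmin) * math.comb(N - K, n - kmin)
    weights = [w]
    for k in range(kmin, kmax):
        # exact integer recurrence between successive hypergeometric weights
        w = w * (K - k) * (n - k) // ((k + 1) * (N - K - n + k + 1))
        weights.append(w)
    return kmin, weights


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test for the table ((a, b), (c, d)).

    Returns (odds_ratio, p_value).  The p-value sums the probabilities of all
    tables with the observed margins whose point probability does not exceed
    the observed table's, with exact integer tie handling.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    N, K, n = a + b + c + d, a + b, a + c
    if N == 0:
        raise ValueError("empty table")
    if b * c > 0:
        odds = (a * d) / (b * c)
    elif a * d > 0:
        odds = math.inf
    else:
        odds = math.nan
    kmin, weights = _hypergeom_weights(N, K, n)
    w_obs = weights[a - kmin]
    num = sum(w for w in weights if w <= w_obs)
    return odds, num / sum(weights)


def bias_table(a: int, A: int, b: int, B: int) -> BiasTable:
    """Build a :class:`BiasTable` with its Fisher test from event/opportunity counts."""
    if A == 0 or B == 0:
        raise ValueError("zero total opportunities in a bias class")
    odds, p = fisher_exact_two_sided(a, A - a, b, B - b)
    return BiasTable(a=a, A=A, b=b, B=B, odds_ratio=odds, p_value=p)
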