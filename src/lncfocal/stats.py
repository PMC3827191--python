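"""Exact small-sample test statistics.

Two tests drive the focal-amplification inference and are implemented
here with exact small-sample paths:

* Wilcoxon rank-sum (Mann-Whitney): exact two-sided p-value by full
  enumeration of the permutation distribution of the rank sum (a
  shift-algorithm dynamic program over doubled midranks, so ties are
  handled exactly) when both groups have at most ``exact_max`` members;
  otherwise a normal approximation with tie and continuity correction.
  The two-sided p doubles the smaller tail, capped at 1.

* Fisher's exact test on a 2x2 table: two-sided p by the
  point-probability method — the sum of hypergeometric point
  probabilities no larger than that of the observed table.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
from scipy import stats as sps

DEFAULT_EXACT_MAX = 12  # per-group size bound for the exact rank-sum path


def _rank_sum_exact_tails(ranks2: np.ndarray, n1: int, w_obs: int) -> tuple[float, float]:
    """P(W <= w_obs) and P(W >= w_obs) for the sum of n1 ranks drawn
    without replacement from ``ranks2`` (ranks doubled to integers).

    Dynamic program over items: dp[k][s] = number of k-subsets with rank
    sum s.  Counts fit in float64 exactly for n <= 24 (C(24,12) < 2^53).
    """
    total = int(ranks2.sum())
    dp = np.zeros((n1 + 1, total + 1))
    dp[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        # iterate k downwards so each item is used at most once
        for k in range(n1, 0, -1):
            dp[k, r:] += dp[k - 1, : total + 1 - r]
    counts = dp[n1]
    n_subsets = counts.sum()
    lo = counts[: w_obs + 1].sum() / n_subsets
    hi = counts[w_obs:].sum() / n_subsets
    return float(lo), float(hi)


def rank_sum_test(
    x: np.ndarray,
    y: np.ndarray,
    exact_max: int = DEFAULT_EXACT_MAX,
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of ``x`` vs ``y``.

    Returns ``(rank_sum_of_x, p_value)``.  Exact enumeration when both
    group sizes are <= ``exact_max``; otherwise normal approximation with
    tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks
    w = float(ranks[:n1].sum())

    if n1 <= exact_max and n2 <= exact_max:
        ranks2 = np.rint(ranks * 2).astype(np.int64)  # integers; ties give equal values
        w2 = int(round(w * 2))
        lo, hi = _rank_sum_exact_tails(ranks2, n1, w2)
        p = min(1.0, 2.0 * min(lo, hi))
        return w, p

    n = n1 + n2
    mean_w = n1 * (n + 1) / 2.0
    # tie-corrected variance of the rank sum
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_w <= 0:
        return w, 1.0
    z = (abs(w - mean_w) - 0.5) / math.sqrt(var_w)  # continuity correction
    z = max(z, 0.0)
    p = 2.0 * sps.norm.sf(z)
    return w, min(1.0, p)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Conditions on the margins and sums hypergeometric point probabilities
    less than or equal to the observed table's probability (with a small
    relative tolerance for floating-point equality).  Degenerate margins
    give p = 1.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("table entries must be non-negative")
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    if n == 0 or row1 in (0, n) or col1 in (0, n):
        return 1.0
    k_min = max(0, row1 + col1 - n)
    k_max = min(row1, col1)
    support = np.arange(k_min, k_max + 1)
    pmf = sps.hypergeom.pmf(support, n, col1, row1)
    p_obs = float(sps.hypergeom.pmf(a, n, col1, row1))
    p = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
    return min(1.0, p)


def fisher_exact_2x2_rational(a: int, b: int, c: int, d: int) -> float:
    """Exact-rational reference implementation of the point-probability
    two-sided Fisher test (enumeration with Fraction arithmetic).

    Slower than :func:`fisher_exact_2x2`; intended for cross-checks on
    small tables.
    """
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if n == 0 or row1 in (0, n) or col1 in (0, n):
        return 1.0

    def pmf(k: int) -> Fraction:
        return Fraction(
            math.comb(col1, k) * math.comb(n - col1, row1 - k), math.comb(n, row1)
        )

    p_obs = pmf(a)
    total = Fraction(0)
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        pk = pmf(k)
        if pk <= p_obs:
            total += pk
    return float(min(Fraction(1), total))
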