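"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: per-basepair scans, itertools
enumeration and rational arithmetic, sharing no code path with the
package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def per_basepair_gene_cna(gene_span, segments):
    """Gene CNA by scanning every basepair of the gene span.

    ``segments`` is a list of (start, end, amplitude) tuples for one
    sample and chromosome.  Returns the minimum amplitude over covered
    basepairs, or NaN when no basepair of the span is covered.
    """
    gs, ge = gene_span
    best = math.inf
    covered = False
    for bp in range(gs, ge):
        for s, e, a in segments:
            if s <= bp < e:
                covered = True
                best = min(best, a)
                break
    return best if covered else float("nan")


def rank_sum_p_enumeration(x, y):
    """Exact two-sided rank-sum p by enumerating every group assignment.

    Doubles the smaller tail of the permutation distribution of the
    group-x rank sum (midranks, so ties are exact).
    """
    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    sums = [sum(c) for c in itertools.combinations(ranks, n1)]
    sums = np.asarray(sums)
    eps = 1e-9
    lo = float((sums <= w_obs + eps).mean())
    hi = float((sums >= w_obs - eps).mean())
    return min(1.0, 2.0 * min(lo, hi))


def welch_t(x, y):
    """Welch's two-sample t statistic, written out longhand."""
    x = list(map(float, x))
    y = list(map(float, y))
    n1, n2 = len(x), len(y)
    m1 = sum(x) / n1
    m2 = sum(y) / n2
    v1 = sum((v - m1) ** 2 for v in x) / (n1 - 1)
    v2 = sum((v - m2) ** 2 for v in y) / (n2 - 1)
    return (m1 - m2) / math.sqrt(v1 / n1 + v2 / n2)
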