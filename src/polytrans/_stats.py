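"""Shared statistical primitives.

All modules use the single BH routine defined here so that multiple-testing
behaviour is identical across the single-cell, bulk and motif stages.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats

__all__ = ["bh_adjust", "rank_sum_test", "EXACT_MAX_N"]

#: largest per-group size for which the rank-sum test enumerates exactly
EXACT_MAX_N = 8


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN inputs propagate to NaN outputs and are excluded from the number of
    tests. The result is invariant to input ordering.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by full enumeration of group assignments.

    Mid-ranks are used for ties; the p-value is the null probability of a
    rank-sum at least as far from its expectation as the observed one.
    Feasible for n_x + n_y <= 16 (C(16,8) = 12870 assignments).
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n = pooled.size
    nx = x.size
    w_obs = ranks[:nx].sum()
    mu = nx * (n + 1) / 2.0
    d_obs = abs(w_obs - mu)
    hits = 0
    total = 0
    for idx in combinations(range(n), nx):
        w = ranks[list(idx)].sum()
        if abs(w - mu) >= d_obs - 1e-9:
            hits += 1
        total += 1
    return hits / total


def rank_sum_test(x, y, exact_max: int = EXACT_MAX_N) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration when both groups have at most `exact_max` observations;
    otherwise the normal approximation with mid-rank tie correction and
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_test requires non-empty groups")
    if x.size <= exact_max and y.size <= exact_max:
        return _exact_rank_sum_p(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return float(res.pvalue)


def rank_sum_test_matrix(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Column-wise two-sided rank-sum p-values (normal approximation).

    `xa` is (n_a, G) and `xb` is (n_b, G); returns G p-values. Used for the
    vectorised large-sample path; small-sample columns should go through
    :func:`rank_sum_test` individually.
    """
    res = stats.mannwhitneyu(xa, xb, alternative="two-sided",
                             method="asymptotic", use_continuity=True, axis=0)
    return np.asarray(res.pvalue, dtype=float)
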