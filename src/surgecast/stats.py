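"""Nonparametric tests for the algorithm-comparison experiment.

Success counts are compared with Fisher's exact test, successful search
times across the three controllers with the Steel--Dwass all-pairs test
(the rank-based analogue of Tukey's HSD), and paired angular-velocity
samples with the two-sided Wilcoxon rank-sum test.

Fisher and the rank-sum test wrap scipy; Steel--Dwass is implemented here
(pairwise midrank statistics referred to the studentized-range
distribution with infinite degrees of freedom).
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = ["fisher_exact", "steel_dwass", "wilcoxon_rank_sum"]


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    The two-sided p sums the hypergeometric probabilities of all tables
    (margins fixed) no more probable than the observed one.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("table entries must be nonnegative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("table has an all-zero margin")
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def _pairwise_rank_stat(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized two-sample midrank statistic for one Steel--Dwass pair.

    The rank sum of the first sample within the pooled pair is centered at
    its null mean and scaled by the exact midrank variance
    n_a*n_b/(N(N-1)) * sum((r_k - (N+1)/2)^2), which reduces to
    n_a*n_b*(N+1)/12 without ties.
    """
    na, nb = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n = na + nb
    w = ranks[:na].sum()
    mean = na * (n + 1) / 2.0
    var = na * nb / (n * (n - 1.0)) * np.sum((ranks - (n + 1) / 2.0) ** 2)
    if var == 0:
        return 0.0
    return float((w - mean) / np.sqrt(var))


def steel_dwass(groups) -> np.ndarray:
    """All-pairs Steel--Dwass comparison; returns a symmetric p-value matrix.

    For each pair of groups the two-sample rank statistic z is computed on
    that pair alone and referred to the studentized range distribution with
    k groups and infinite degrees of freedom: p = P(Q_{k,inf} >= |z|*sqrt(2)).
    For k = 2 this reduces to the two-sided normal rank-sum p.  Ties are
    handled by midranks with the exact variance correction.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 samples")
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            z = _pairwise_rank_stat(groups[i], groups[j])
            pij = float(sps.studentized_range.sf(abs(z) * np.sqrt(2.0), k, np.inf))
            p[i, j] = p[j, i] = min(1.0, pij)
    return p


def wilcoxon_rank_sum(a, b) -> float:
    """Two-sided Wilcoxon rank-sum p (normal approximation, tie-corrected)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need at least 2 values")
    if np.all(np.concatenate([a, b]) == np.concatenate([a, b])[0]):
        return 1.0  # all values tied: no evidence either way
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)
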