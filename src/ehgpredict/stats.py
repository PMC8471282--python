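"""Hypothesis tests used throughout: the Wilcoxon rank-sum test for two
independent samples and the Friedman test for multiple related samples.

Both are two-sided.  Post-hoc pairwise model comparisons are not
multiplicity-corrected by default; Holm correction is available as an
option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str


def ranksum_test(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when n_x + n_y <= 12 and there are no ties,
    otherwise the normal approximation with tie and continuity
    corrections.  Two samples with all values identical give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return TestResult(float(x.size * y.size / 2.0), 1.0,
                          "ranksum_normal_approx")
    has_ties = np.unique(pooled).size < pooled.size
    if x.size + y.size <= 12 and not has_ties:
        res = sstats.mannwhitneyu(x, y, alternative="two-sided",
                                  method="exact")
        return TestResult(float(res.statistic), float(res.pvalue),
                          "ranksum_exact")
    res = sstats.mannwhitneyu(x, y, alternative="two-sided",
                              method="asymptotic", use_continuity=True)
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                      "ranksum_normal_approx")


def friedman_test(scores) -> TestResult:
    """Friedman chi-square test on a (k models x b blocks) score matrix.

    Within-block ranks with average ranks for ties; the tie-corrected
    statistic SS_treatment / SS_error is chi-square with k-1 degrees of
    freedom.  Works for k >= 2 (scipy's version needs k >= 3).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise ValueError("scores must be a 2-D (k x b) matrix")
    k, b = scores.shape
    if k < 2 or b < 2:
        raise ValueError("need at least 2 models and 2 blocks")
    ranks = np.apply_along_axis(sstats.rankdata, 0, scores)  # within blocks
    rbar = (k + 1) / 2.0
    mean_ranks = ranks.mean(axis=1)
    ss_t = b * float(((mean_ranks - rbar) ** 2).sum())
    ss_e = float(((ranks - rbar) ** 2).sum()) / (b * (k - 1))
    if ss_e == 0.0:
        return TestResult(0.0, 1.0, "friedman_chi2")
    stat = ss_t / ss_e
    p = float(sstats.chi2.sf(stat, df=k - 1))
    return TestResult(float(stat), p, "friedman_chi2")


def signed_rank_test(x, y) -> TestResult:
    """Paired Wilcoxon signed-rank alternative for per-partition metrics."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.all(x == y):
        return TestResult(0.0, 1.0, "signed_rank")
    res = sstats.wilcoxon(x, y)
    return TestResult(float(res.statistic), float(res.pvalue), "signed_rank")


def holm_correction(p_values):
    """Holm step-down adjusted p-values (optional post-hoc correction)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    adj = np.empty_like(p)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (p.size - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj
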