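"""Nonparametric comparisons between optimizers.

Two tests are exposed, matching the usual benchmarking protocol for
stochastic optimizers: the two-sided Wilcoxon rank-sum (Mann-Whitney) test
between two algorithms' repeated-run scores, and the Friedman test with
average ranks across (image, K) blocks for three or more algorithms.  Both
use midranks for ties and a 5% significance level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["RankSumResult", "FriedmanResult", "wilcoxon_rank_sum", "friedman"]

ALPHA = 0.05


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # rank sum W of the first sample (midranks)
    p_value: float
    reject_at_005: bool


@dataclass(frozen=True)
class FriedmanResult:
    average_ranks: np.ndarray  # one per method, rank 1 = best
    statistic: float
    p_value: float


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test of a location shift between two samples.

    The statistic is the midrank sum of the first sample in the pooled
    ranking.  The p-value is exact (full enumeration) when both samples have
    fewer than 10 observations and no ties are present, otherwise the
    normal approximation with continuity correction is used.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w = float(ranks[: x.size].sum())
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) < 10 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    p = float(min(1.0, res.pvalue))
    return RankSumResult(statistic=w, p_value=p, reject_at_005=p < ALPHA)


def friedman(blocks: np.ndarray, larger_is_better: bool = True) -> FriedmanResult:
    """Friedman test over a B x k matrix of method scores (B blocks, k methods).

    Each block is ranked with midranks (rank 1 = best according to
    ``larger_is_better``); average ranks are returned per method and the
    p-value comes from the tie-corrected chi-square approximation
    ``chi2 = (k-1) [sum_j R_j^2 - B^2 k(k+1)^2/4] / [A - B k(k+1)^2/4]``
    with ``A`` the sum of squared within-block ranks (which reduces to the
    classical statistic when no ties occur).
    """
    m = np.asarray(blocks, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a B x k matrix with B >= 2 blocks and k >= 2 methods")
    B, k = m.shape
    scores = -m if larger_is_better else m
    ranks = np.apply_along_axis(sps.rankdata, 1, scores)
    avg_ranks = ranks.mean(axis=0)
    col_sums = ranks.sum(axis=0)
    a = float(np.sum(ranks**2))
    correction = B * k * (k + 1) ** 2 / 4.0
    denom = a - correction
    if denom <= 0:  # complete ties: no evidence against equality
        return FriedmanResult(average_ranks=avg_ranks, statistic=0.0, p_value=1.0)
    stat = (k - 1) * (float(np.sum(col_sums**2)) - B * correction) / denom
    p = float(sps.chi2.sf(stat, k - 1))
    return FriedmanResult(average_ranks=avg_ranks, statistic=float(stat), p_value=p)
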