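"""Group comparisons and correlation statistics.

Welch's (unequal-variance) two-tailed t-test compares segregation and
normalized overlap between network groups; Pearson correlation with a
two-tailed p from the t transform (n−2 df) relates overlap to dynamic
or behavioral measures. p-values are reported raw (no multiple-testing
correction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
from scipy import stats as sps

from ._util import child_seeds
from .community_metrics import segregation_score
from .link_communities import normalized_overlap_score

__all__ = ["GroupComparison", "pearson", "welch_t", "compare_groups"]


@dataclass(frozen=True)
class GroupComparison:
    segregation_a: np.ndarray
    segregation_b: np.ndarray
    overlap_a: np.ndarray
    overlap_b: np.ndarray
    t_segregation: float
    p_segregation: float
    t_overlap: float
    p_overlap: float


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r with a two-tailed p-value (t transform, n−2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with at least 3 points")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-tailed Welch t-test (unequal variances)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("degenerate variance: both groups are constant")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    group_a: Sequence[nx.Graph],
    group_b: Sequence[nx.Graph],
    seed: int = 0,
    n_null: int = 10,
    louvain_runs: int = 10,
) -> GroupComparison:
    """Per-network segregation and normalized overlap, compared by Welch t.

    Mirrors the group-level contrast between network families: each
    network contributes its Louvain modularity and its overlap score
    normalized by degree-preserving random nulls.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    seeds = child_seeds(seed, 2 * (len(group_a) + len(group_b)))
    k = 0

    def score(graphs):
        nonlocal k
        seg, ov = [], []
        for g in graphs:
            seg.append(segregation_score(g, seed=int(seeds[k]), n_runs=louvain_runs))
            ov.append(normalized_overlap_score(g, n_null=n_null, seed=int(seeds[k + 1])).normalized_overlap)
            k += 2
        return np.array(seg), np.array(ov)

    seg_a, ov_a = score(group_a)
    seg_b, ov_b = score(group_b)
    t_seg, p_seg = welch_t(seg_a, seg_b)
    t_ov, p_ov = welch_t(ov_a, ov_b)
    return GroupComparison(
        segregation_a=seg_a,
        segregation_b=seg_b,
        overlap_a=ov_a,
        overlap_b=ov_b,
        t_segregation=t_seg,
        p_segregation=p_seg,
        t_overlap=t_ov,
        p_overlap=p_ov,
    )
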