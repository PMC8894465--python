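"""Sliding-window functional connectivity and dynamic flexibility.

A nodes × time panel is converted into a sequence of windowed Pearson
correlation matrices (window shifted by a fixed step across the scan).
Communities are detected independently in each window (weighted Louvain
on the positive correlations) and community labels are matched between
consecutive windows by an optimal one-to-one assignment maximizing
label-set Jaccard overlap, so that a label change reflects a genuine
change of module allegiance rather than an arbitrary relabeling. The
flexibility of a node is the fraction of consecutive-window transitions
at which its matched label changes; the mean over nodes is the mean
dynamic flexibility of the panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment

from ._util import child_seeds
from .community_metrics import louvain_partition

logger = logging.getLogger(__name__)

__all__ = [
    "TimeSeriesPanel",
    "DynamicConnectivity",
    "FlexibilityResult",
    "window_count",
    "window_samples_from_seconds",
    "sliding_window_fc",
    "dynamic_communities",
    "flexibility",
]


@dataclass(frozen=True)
class TimeSeriesPanel:
    """Nodes × time numeric matrix with a sampling interval in seconds."""

    values: np.ndarray
    sampling_interval: float

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] < 2:
            raise ValueError("panel must be a 2-D (nodes x time) matrix with >= 2 nodes")
        if not np.isfinite(v).all():
            raise ValueError("panel contains missing or non-finite values")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        object.__setattr__(self, "values", v)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class DynamicConnectivity:
    """N × N × W tensor of windowed correlation matrices."""

    tensor: np.ndarray
    window_samples: int
    step_samples: int

    @property
    def n_windows(self) -> int:
        return self.tensor.shape[2]


@dataclass(frozen=True)
class FlexibilityResult:
    per_node_flexibility: np.ndarray
    mean_flexibility: float


def window_count(T: int, window_samples: int, step_samples: int = 1) -> int:
    """Number of fully-contained window start positions."""
    if window_samples > T:
        raise ValueError("window longer than the series")
    if step_samples < 1:
        raise ValueError("step must be >= 1 sample")
    return (T - window_samples) // step_samples + 1


def window_samples_from_seconds(window_seconds: float, sampling_interval: float) -> int:
    """Window length in samples: round(window_seconds / sampling_interval).

    The canonical resting-state case (30 s window, 0.72 s sampling)
    yields 42 samples, hence 4759 windows on a 4800-sample scan at a
    one-sample step.
    """
    w = int(round(window_seconds / sampling_interval))
    if w < 2:
        raise ValueError("window must span at least two samples")
    return w


def sliding_window_fc(
    panel: TimeSeriesPanel,
    window_seconds: float = 30.0,
    step_seconds: float | None = None,
) -> DynamicConnectivity:
    """Windowed Pearson correlation tensor of a panel.

    ``step_seconds`` defaults to one sampling interval. Node pairs where
    either node has zero variance within a window get correlation 0 (a
    logged count); diagonals are 1.
    """
    w = window_samples_from_seconds(window_seconds, panel.sampling_interval)
    step = 1 if step_seconds is None else int(round(step_seconds / panel.sampling_interval))
    if step < 1:
        raise ValueError("step must be at least one sample")
    n, t = panel.n_nodes, panel.n_samples
    n_win = window_count(t, w, step)
    tensor = np.empty((n, n, n_win))
    n_degenerate = 0
    for k in range(n_win):
        sl = panel.values[:, k * step : k * step + w]
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(sl)
        bad = ~np.isfinite(c)
        n_degenerate += int(np.count_nonzero(np.triu(bad, k=1)))
        c[bad] = 0.0
        np.fill_diagonal(c, 1.0)
        tensor[:, :, k] = c
    if n_degenerate > 0:
        logger.warning("zero-variance windows: %d degenerate correlations set to 0", n_degenerate)
    return DynamicConnectivity(tensor=tensor, window_samples=w, step_samples=step)


def _match_labels(prev: np.ndarray, cur: np.ndarray, next_fresh: int) -> tuple[np.ndarray, int]:
    """Relabel ``cur`` to maximize Jaccard agreement with ``prev``.

    One-to-one assignment on the community-overlap contingency table;
    communities without a positive-overlap partner get fresh labels.
    """
    prev_labels = np.unique(prev)
    cur_labels = np.unique(cur)
    count = np.zeros((prev_labels.size, cur_labels.size))
    for a, pa in enumerate(prev_labels):
        in_a = prev == pa
        for b, pb in enumerate(cur_labels):
            count[a, b] = np.sum(in_a & (cur == pb))
    sizes_a = np.array([(prev == pa).sum() for pa in prev_labels], dtype=float)
    sizes_b = np.array([(cur == pb).sum() for pb in cur_labels], dtype=float)
    jac = count / (sizes_a[:, None] + sizes_b[None, :] - count)
    rows, cols = linear_sum_assignment(-jac)
    mapping = {}
    for a, b in zip(rows, cols):
        if count[a, b] > 0:
            mapping[cur_labels[b]] = prev_labels[a]
    out = np.empty_like(cur)
    for pb in cur_labels:
        if pb in mapping:
            out[cur == pb] = mapping[pb]
        else:
            out[cur == pb] = next_fresh
            next_fresh += 1
    return out, next_fresh


def dynamic_communities(dc: DynamicConnectivity, gamma: float = 1.0, seed: int = 0,
                        louvain_runs: int = 1) -> np.ndarray:
    """Per-window community labels (N × W), identity-tracked across windows.

    Each window's positive-correlation graph is partitioned by weighted
    Louvain at resolution gamma; labels are then propagated forward by
    maximum-Jaccard matching so that allegiance changes are meaningful.
    """
    n, _, w = dc.tensor.shape
    if w < 2:
        raise ValueError("need at least two windows to track communities")
    seeds = child_seeds(seed, w)
    labels = np.empty((n, w), dtype=int)
    next_fresh = 0
    for k in range(w):
        mat = dc.tensor[:, :, k].copy()
        np.fill_diagonal(mat, 0.0)
        mat[mat < 0] = 0.0
        if not (mat > 0).any():
            raise ValueError(f"window {k}: no positive correlations to partition")
        g = nx.from_numpy_array(mat)
        part = louvain_partition(g, gamma=gamma, seed=int(seeds[k]),
                                 n_runs=louvain_runs, weight="weight")
        raw = np.array([part.assignment[i] for i in range(n)])
        if k == 0:
            labels[:, 0] = raw
            next_fresh = int(raw.max()) + 1
        else:
            labels[:, k], next_fresh = _match_labels(labels[:, k - 1], raw, next_fresh)
    return labels


def flexibility(labels: np.ndarray) -> FlexibilityResult:
    """Per-node rate of community-allegiance change between windows."""
    labels = np.asarray(labels)
    if labels.ndim != 2 or labels.shape[1] < 2:
        raise ValueError("labels must be N x W with W >= 2")
    changes = labels[:, 1:] != labels[:, :-1]
    per_node = changes.mean(axis=1)
    return FlexibilityResult(per_node_flexibility=per_node, mean_flexibility=float(per_node.mean()))
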