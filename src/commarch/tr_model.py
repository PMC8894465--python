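"""Topological reinforcement (TR): Hebbian-like rewiring toward modularity.

Starting from a connected random graph, each step (i) samples ⌊N/2⌋
nodes that are neither isolated nor fully connected, (ii) adds, for
each sampled node, one link to the non-neighbor sharing the most common
neighbors with it (all additions scored against the pre-step graph and
applied as one batch; duplicate proposals collapse), and (iii) deletes
uniformly random existing links — resampling any deletion that would
disconnect the graph — until the original edge count is restored. Node
count and link density are therefore exactly conserved along the
trajectory, while repeated reinforcement of shared neighborhoods drives
the emergence of modular structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from ._util import child_seeds, ordered_nodes
from .communication import activated_ratio, global_efficiency, local_efficiency
from .community_metrics import segregation_score
from .graph_core import density
from .link_communities import link_community_cover, overlap_score
from .null_models import _still_reachable

logger = logging.getLogger(__name__)

__all__ = ["TRTrajectory", "topological_overlap", "tr_step", "tr_evolve", "tr_ensemble_mean"]

ALL_METRICS = ("segregation", "overlap", "global_eff", "local_eff", "activated_ratio")


@dataclass
class TRTrajectory:
    """Per-step metric records of one TR evolution run."""

    metrics: pd.DataFrame  # one row per step (step 0 = initial network)
    n_steps: int
    seed: int
    snapshots: list = field(default_factory=list)  # optional per-step graphs


def topological_overlap(g: nx.Graph, i, j) -> int:
    """Number of common neighbors of two distinct nodes."""
    if i == j:
        raise ValueError("topological overlap needs two distinct nodes")
    if i not in g or j not in g:
        raise ValueError(f"unknown node among ({i!r}, {j!r})")
    return len(set(g.neighbors(i)) & set(g.neighbors(j)))


def tr_step(g: nx.Graph, seed: int = 0, retry_factor: int = 100) -> nx.Graph:
    """One TR rewiring step; preserves node count and edge count exactly."""
    nodes = ordered_nodes(g)
    n = len(nodes)
    a = nx.to_numpy_array(g, nodelist=nodes, weight=None).astype(bool)
    deg = a.sum(axis=1)
    eligible = np.flatnonzero((deg > 0) & (deg < n - 1))
    if eligible.size == 0:
        logger.warning("no eligible nodes for TR step; returning unchanged copy")
        return g.copy()
    rng = np.random.default_rng(seed)
    k_sel = min(n // 2, eligible.size)
    selected = rng.choice(eligible, size=k_sel, replace=False)

    common = (a.astype(np.int32) @ a.astype(np.int32).T)  # common-neighbor counts
    proposals = set()
    for u in selected:
        candidates = np.flatnonzero(~a[u])
        candidates = candidates[candidates != u]
        scores = common[u, candidates]
        best = scores.max()
        winners = candidates[scores == best]
        v = int(winners[rng.integers(0, winners.size)])  # random tie-break
        proposals.add((min(int(u), v), max(int(u), v)))

    new_edges = [e for e in sorted(proposals) if not a[e[0], e[1]]]
    out = g.copy()
    out.add_edges_from((nodes[x], nodes[y]) for x, y in new_edges)
    n_added = len(new_edges)
    if n_added == 0:
        return out

    adj = {v: set(out.neighbors(v)) for v in out.nodes}
    edge_list = list(out.edges)
    budget = retry_factor * n_added
    deleted = 0
    while deleted < n_added:
        if budget <= 0:
            raise RuntimeError("TR step: deletion retry budget exhausted without keeping connectivity")
        pos = int(rng.integers(0, len(edge_list)))
        u, v = edge_list[pos]
        adj[u].discard(v)
        adj[v].discard(u)
        if _still_reachable(adj, u, v):
            edge_list[pos] = edge_list[-1]
            edge_list.pop()
            out.remove_edge(u, v)
            deleted += 1
        else:
            adj[u].add(v)
            adj[v].add(u)
            budget -= 1
    return out


def _measure(g: nx.Graph, metrics: Sequence[str], seed: int,
             theta: float, seed_fraction: float, n_rep: int, louvain_runs: int) -> dict:
    row = {"density": density(g)}
    if "segregation" in metrics:
        row["segregation"] = segregation_score(g, seed=seed, n_runs=louvain_runs)
    if "overlap" in metrics:
        row["overlap"] = overlap_score(g, link_community_cover(g))
    if "global_eff" in metrics:
        row["global_eff"] = global_efficiency(g)
    if "local_eff" in metrics:
        row["local_eff"] = local_efficiency(g)
    if "activated_ratio" in metrics:
        row["activated_ratio"] = activated_ratio(
            g, seed_fraction=seed_fraction, theta=theta, n_rep=n_rep, seed=seed
        )
    return row


def tr_evolve(
    g0: nx.Graph,
    n_steps: int = 60,
    seed: int = 0,
    metrics: Sequence[str] = ALL_METRICS,
    theta: float = 0.5,
    seed_fraction: float = 0.32,
    diffusion_reps: int = 20,
    louvain_runs: int = 5,
    keep_snapshots: bool = False,
) -> TRTrajectory:
    """Evolve a connected graph for ``n_steps`` TR steps, recording metrics.

    Row ``step=0`` describes the initial network; density is recorded at
    every step and is exactly conserved by construction.
    """
    if not nx.is_connected(g0):
        raise ValueError("TR evolution requires a connected initial graph")
    unknown = set(metrics) - set(ALL_METRICS)
    if unknown:
        raise ValueError(f"unknown metrics: {sorted(unknown)}")
    step_seeds = child_seeds(seed, 2 * (n_steps + 1))
    g = g0.copy()
    rows = []
    snaps = []
    for step in range(n_steps + 1):
        if step > 0:
            g = tr_step(g, seed=int(step_seeds[2 * step]))
        row = _measure(
            g, metrics, seed=int(step_seeds[2 * step + 1]),
            theta=theta, seed_fraction=seed_fraction,
            n_rep=diffusion_reps, louvain_runs=louvain_runs,
        )
        row["step"] = step
        rows.append(row)
        if keep_snapshots:
            snaps.append(g.copy())
    frame = pd.DataFrame(rows).set_index("step").reset_index()
    return TRTrajectory(metrics=frame, n_steps=n_steps, seed=seed, snapshots=snaps)


def tr_ensemble_mean(
    n_networks: int = 50,
    N: int = 164,
    mean_degree: float = 16.0,
    n_steps: int = 60,
    seed: int = 0,
    metrics: Sequence[str] = ALL_METRICS,
    **kwargs,
) -> pd.DataFrame:
    """Per-step metrics averaged over an ensemble of TR runs from ER starts.

    Disconnected ER draws are redrawn from the seed stream (the model is
    defined for connected initial networks).
    """
    from .synthetic_networks import generate_er

    seeds = child_seeds(seed, 4 * n_networks)
    frames = []
    used = 0
    for s in seeds:
        g0 = generate_er(N, mean_degree, seed=int(s))
        if not nx.is_connected(g0):
            continue
        traj = tr_evolve(g0, n_steps=n_steps, seed=int(s) + 1, metrics=metrics, **kwargs)
        frames.append(traj.metrics)
        used += 1
        if used == n_networks:
            break
    if used < n_networks:
        raise RuntimeError(f"only {used}/{n_networks} connected ER starts obtained")
    stacked = pd.concat(frames)
    return stacked.groupby("step", as_index=False).mean()
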