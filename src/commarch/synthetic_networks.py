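"""Planted-partition and Erdős–Rényi generators; the architecture sweep.

The planted-partition model places an edge independently with
probability ``p_in`` inside each of M equal-size modules and ``p_out``
between modules. Sweeping (p_in, p_out) produces networks spanning the
full range of community segregation, over which the segregation and
overlap scores are measured and averaged over replicates — the in-silico
experiment relating the two axes of community architecture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from ._util import child_seeds
from .community_metrics import louvain_partition
from .link_communities import link_community_cover, maintains_segregated_structure, overlap_score

logger = logging.getLogger(__name__)

__all__ = ["ModularSpec", "generate_modular", "generate_er", "sweep_architecture", "rescale_over_max"]


@dataclass(frozen=True)
class ModularSpec:
    N: int
    M: int
    p_in: float
    p_out: float
    seed: int = 0

    def __post_init__(self):
        if self.N % self.M != 0:
            raise ValueError(f"N={self.N} not divisible by M={self.M}")
        if not (0 <= self.p_out <= 1 and 0 <= self.p_in <= 1):
            raise ValueError("edge probabilities must lie in [0, 1]")


def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def generate_modular(spec: ModularSpec) -> nx.Graph:
    """Planted-partition graph with equal-size modules (nodes 0..N-1).

    Module of node v is ``v // (N/M)``; stored on the graph as the
    ``planted_module`` node attribute.
    """
    n, m = spec.N, spec.M
    size = n // m
    rng = np.random.default_rng(spec.seed)
    iu, ju = _pair_indices(n)
    same = (iu // size) == (ju // size)
    p = np.where(same, spec.p_in, spec.p_out)
    keep = rng.random(iu.shape[0]) < p
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(zip(iu[keep].tolist(), ju[keep].tolist()))
    nx.set_node_attributes(g, {v: int(v // size) for v in range(n)}, "planted_module")
    return g


def generate_er(N: int, mean_degree: float, seed: int = 0) -> nx.Graph:
    """G(N, p) with p = mean_degree / (N − 1); no self-loops."""
    if not (0 <= mean_degree <= N - 1):
        raise ValueError("mean_degree must lie in [0, N-1]")
    p = mean_degree / (N - 1) if N > 1 else 0.0
    rng = np.random.default_rng(seed)
    iu, ju = _pair_indices(N)
    keep = rng.random(iu.shape[0]) < p
    g = nx.Graph()
    g.add_nodes_from(range(N))
    g.add_edges_from(zip(iu[keep].tolist(), ju[keep].tolist()))
    return g


def _score_component(g: nx.Graph) -> nx.Graph | None:
    """Graph to score: largest connected component, or None if edgeless."""
    if g.number_of_edges() == 0:
        return None
    if not nx.is_connected(g):
        comp = max(nx.connected_components(g), key=len)
        logger.info("scoring largest component (%d of %d nodes)", len(comp), g.number_of_nodes())
        g = g.subgraph(comp).copy()
    return g


def sweep_architecture(
    N: int,
    M: int,
    p_in_grid,
    p_out_grid,
    replicates: int = 5,
    seed: int = 0,
    louvain_runs: int = 5,
) -> pd.DataFrame:
    """Mean segregation/overlap over a (p_in, p_out) grid.

    Returns one row per grid cell with columns ``p_in, p_out,
    segregation, overlap, n_communities, maintains_segregation``
    averaged over ``replicates`` seeded networks. Disconnected draws are
    scored on their largest connected component.
    """
    p_in_grid = list(p_in_grid)
    p_out_grid = list(p_out_grid)
    if not p_in_grid or not p_out_grid:
        raise ValueError("grids must be non-empty")
    n_cells = len(p_in_grid) * len(p_out_grid)
    seeds = child_seeds(seed, n_cells * replicates).reshape(n_cells, replicates)
    rows = []
    cell = 0
    for p_in in p_in_grid:
        for p_out in p_out_grid:
            seg, ov, ncomm, keeps = [], [], [], []
            for r in range(replicates):
                s = int(seeds[cell, r])
                g = generate_modular(ModularSpec(N=N, M=M, p_in=p_in, p_out=p_out, seed=s))
                scored = _score_component(g)
                if scored is None:
                    continue
                part = louvain_partition(scored, seed=s, n_runs=louvain_runs)
                cover = link_community_cover(scored)
                seg.append(part.Q)
                ov.append(overlap_score(scored, cover))
                ncomm.append(cover.n_communities)
                keeps.append(maintains_segregated_structure(cover, M))
            rows.append(
                {
                    "p_in": p_in,
                    "p_out": p_out,
                    "segregation": float(np.mean(seg)) if seg else np.nan,
                    "overlap": float(np.mean(ov)) if ov else np.nan,
                    "n_communities": float(np.mean(ncomm)) if ncomm else np.nan,
                    "maintains_segregation": float(np.mean(keeps)) if keeps else np.nan,
                }
            )
            cell += 1
    return pd.DataFrame(rows)


def rescale_over_max(df: pd.DataFrame, column: str) -> pd.DataFrame:
    """Divide a sweep column by its maximum (per-configuration rescaling)."""
    out = df.copy()
    peak = out[column].max()
    if not np.isfinite(peak) or peak == 0:
        raise ValueError(f"cannot rescale column {column!r}: max is {peak}")
    out[column] = out[column] / peak
    return out
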