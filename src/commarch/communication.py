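"""Communication efficiency: routing-based and diffusion-based measures.

Routing-based: global efficiency (mean inverse shortest-path length
over node pairs) and local efficiency (the same quantity within each
node's neighbor subgraph, averaged over nodes). Diffusion-based: the
linear threshold model — an inactive node activates once the fraction
of its neighbors that are active reaches a threshold θ (each neighbor
contributes 1/degree of the receiving node), run synchronously to a
fixed point; the steady-state activated-node ratio summarizes how
cheaply activity spreads through the whole system.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from ._util import child_seeds, ordered_nodes

__all__ = [
    "DiffusionResult",
    "global_efficiency",
    "local_efficiency",
    "linear_threshold",
    "activated_ratio",
]


@dataclass(frozen=True)
class DiffusionResult:
    seed_set: frozenset
    threshold: float
    activated_final: frozenset
    activated_ratio: float
    n_rounds: int


def global_efficiency(g: nx.Graph) -> float:
    """Mean over ordered node pairs of 1/shortest-path length.

    Disconnected pairs contribute 0; the value lies in [0, 1] and equals
    1 exactly for a complete graph.
    """
    if g.number_of_nodes() < 2:
        raise ValueError("global efficiency needs at least two nodes")
    return nx.global_efficiency(g)


def local_efficiency(g: nx.Graph) -> float:
    """Mean over nodes of the neighbor-subgraph global efficiency.

    Nodes of degree < 2 contribute 0 (Latora–Marchiori convention).
    """
    if g.number_of_nodes() < 1:
        raise ValueError("local efficiency needs at least one node")
    return nx.local_efficiency(g)


def linear_threshold(
    g: nx.Graph,
    seeds,
    theta: float,
    strict_threshold: bool = False,
) -> DiffusionResult:
    """Synchronous linear-threshold diffusion to its fixed point.

    A node with at least one active neighbor activates when the summed
    influence (1/degree per active neighbor) reaches θ — ``>= theta`` by
    default, strictly ``> theta`` with ``strict_threshold``. Activation
    is permanent, so the fixed point does not depend on update order.
    """
    if not (0 <= theta <= 1):
        raise ValueError("theta must lie in [0, 1]")
    seeds = frozenset(seeds)
    if not seeds:
        raise ValueError("seed set must be non-empty")
    unknown = seeds - set(g.nodes)
    if unknown:
        raise ValueError(f"seed nodes not in graph: {sorted(map(str, unknown))[:3]}")
    nodes = ordered_nodes(g)
    index = {v: i for i, v in enumerate(nodes)}
    a = nx.to_numpy_array(g, nodelist=nodes, weight=None)
    deg = a.sum(axis=1)
    safe_deg = np.where(deg > 0, deg, 1.0)
    active = np.zeros(len(nodes), dtype=bool)
    active[[index[s] for s in seeds]] = True
    rounds = 0
    while True:
        n_active_neighbors = a @ active
        influence = n_active_neighbors / safe_deg
        meets = influence > theta if strict_threshold else influence >= theta
        newly = (~active) & (n_active_neighbors > 0) & meets
        if not newly.any():
            break
        active |= newly
        rounds += 1
    final = frozenset(nodes[i] for i in np.flatnonzero(active))
    return DiffusionResult(
        seed_set=seeds,
        threshold=theta,
        activated_final=final,
        activated_ratio=len(final) / len(nodes),
        n_rounds=rounds,
    )


def activated_ratio(
    g: nx.Graph,
    seed_fraction: float,
    theta: float = 0.5,
    n_rep: int = 20,
    seed: int = 0,
    strict_threshold: bool = False,
) -> float:
    """Mean steady-state activated ratio over random seed sets.

    Each repetition seeds ``round(seed_fraction · N)`` (at least one)
    uniformly chosen nodes and runs the diffusion to its fixed point.
    """
    if not (0 < seed_fraction <= 1):
        raise ValueError("seed_fraction must lie in (0, 1]")
    nodes = ordered_nodes(g)
    k = max(1, int(round(seed_fraction * len(nodes))))
    ratios = []
    for s in child_seeds(seed, n_rep):
        rng = np.random.default_rng(int(s))
        chosen = rng.choice(len(nodes), size=k, replace=False)
        res = linear_threshold(g, (nodes[i] for i in chosen), theta, strict_threshold)
        ratios.append(res.activated_ratio)
    return float(np.mean(ratios))
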