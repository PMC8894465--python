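"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: modularity is
maximized by exhaustive enumeration of set partitions, the best link
community cut is found by rescanning every dendrogram threshold with
scipy's fcluster, and the linear-threshold fixed point is recomputed by
asynchronous random-order simulation.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster


def set_partitions(items):
    """All partitions of a list (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [[first] + partition[i]] + partition[i + 1 :]
        yield partition + [[first]]


def direct_modularity(g: nx.Graph, blocks, gamma: float = 1.0) -> float:
    """Textbook Q = Σ_c [L_c/m − γ(d_c/2m)²] evaluated from scratch."""
    m = g.number_of_edges()
    q = 0.0
    for block in blocks:
        block = set(block)
        lc = sum(1 for u, v in g.edges if u in block and v in block)
        dc = sum(g.degree(n) for n in block)
        q += lc / m - gamma * (dc / (2 * m)) ** 2
    return q


def brute_force_max_modularity(g: nx.Graph, gamma: float = 1.0) -> float:
    """Exhaustive-enumeration modularity optimum (feasible for <= 8 nodes)."""
    return max(direct_modularity(g, blocks, gamma) for blocks in set_partitions(list(g.nodes)))


def direct_partition_density(g: nx.Graph, edge_labels: dict) -> float:
    """D evaluated from scratch on an edge -> label mapping."""
    m = g.number_of_edges()
    groups: dict = {}
    for e, lab in edge_labels.items():
        groups.setdefault(lab, []).append(e)
    total = 0.0
    for edges in groups.values():
        mc = len(edges)
        nc = len({n for e in edges for n in e})
        if nc > 2:
            total += mc * (mc - (nc - 1)) / ((nc - 2) * (nc - 1))
    return 2.0 / m * total


def best_cut_density(g: nx.Graph, dendrogram: np.ndarray, edges) -> float:
    """Max partition density over every dendrogram cut (fcluster rescan)."""
    best = 0.0  # all-singleton cut
    heights = sorted(set(dendrogram[:, 2])) if len(dendrogram) else []
    for h in heights:
        flat = fcluster(dendrogram, t=h, criterion="distance")
        labels = {e: int(c) for e, c in zip(edges, flat)}
        best = max(best, direct_partition_density(g, labels))
    return best


def async_linear_threshold(g: nx.Graph, seeds, theta: float, seed: int) -> frozenset:
    """Fixed point by asynchronous random-order updates (monotone oracle)."""
    rng = np.random.default_rng(seed)
    active = set(seeds)
    nodes = list(g.nodes)
    changed = True
    while changed:
        changed = False
        order = rng.permutation(len(nodes))
        for i in order:
            v = nodes[i]
            if v in active:
                continue
            deg = g.degree(v)
            if deg == 0:
                continue
            n_active = sum(1 for u in g.neighbors(v) if u in active)
            if n_active > 0 and n_active / deg >= theta:
                active.add(v)
                changed = True
    return frozenset(active)
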