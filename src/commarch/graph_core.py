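"""Graph data model and I/O.

All analyses in this package operate on simple undirected unweighted
graphs (``networkx.Graph`` without self-loops). Weighted graphs appear
only as the *input* to :func:`binarize_to_density`, emulating
streamline-count connectivity matrices that are thresholded to a fixed
link density before any topological analysis.

Isolated nodes are representable: the node roster of a graph may exceed
the set of nodes that appear in edges (needed so that overlap scoring
can guarantee every node at least one community membership).
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from ._util import canonical_edge, node_sort_key, ordered_nodes

logger = logging.getLogger(__name__)

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "read_adjacency",
    "write_adjacency",
    "density",
    "binarize_to_density",
    "consensus_network",
]


def density(g: nx.Graph) -> float:
    """Link density 2m / (N(N-1)) of a simple undirected graph."""
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def read_edge_list(path) -> nx.Graph:
    """Read a whitespace-separated edge list into a simple graph.

    Lines starting with ``#`` are comments. Duplicate edges (in either
    orientation) collapse to one; self-loop lines are dropped with a
    warning and contribute no node.

    Raises
    ------
    ValueError
        If a non-comment line has fewer than two tokens.
    """
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            if len(tokens) < 2:
                raise ValueError(f"{path}: malformed edge line {lineno}: {line!r}")
            u, v = tokens[0], tokens[1]
            if u == v:
                logger.warning("%s: dropping self-loop at line %d (%s)", path, lineno, u)
                continue
            g.add_edge(u, v)
    return g


def write_edge_list(g: nx.Graph, path) -> None:
    """Write one canonical edge per line; isolated nodes as ``# node X``."""
    with open(path, "w") as fh:
        for u, v in sorted(
            (canonical_edge(u, v) for u, v in g.edges),
            key=lambda e: (node_sort_key(e[0]), node_sort_key(e[1])),
        ):
            fh.write(f"{u} {v}\n")
        for n in ordered_nodes(g):
            if g.degree(n) == 0:
                fh.write(f"# node {n}\n")


def read_adjacency(path, delimiter=None) -> nx.Graph:
    """Read a square delimited numeric matrix (header row of node labels).

    Returns a weighted graph: symmetric positive entries become edges
    with a ``weight`` attribute; the diagonal is ignored.
    """
    with open(path) as fh:
        header = fh.readline().split(delimiter)
        labels = [h.strip() for h in header if h.strip()]
        mat = np.loadtxt(fh, delimiter=delimiter)
    mat = np.atleast_2d(mat)
    n = len(labels)
    if mat.shape != (n, n):
        raise ValueError(f"{path}: matrix shape {mat.shape} does not match {n} header labels")
    if not np.allclose(mat, mat.T):
        raise ValueError(f"{path}: adjacency matrix is not symmetric")
    g = nx.Graph()
    g.add_nodes_from(labels)
    for i in range(n):
        for j in range(i + 1, n):
            if mat[i, j] != 0:
                g.add_edge(labels[i], labels[j], weight=float(mat[i, j]))
    return g


def write_adjacency(g: nx.Graph, path, delimiter="\t") -> None:
    nodes = ordered_nodes(g)
    mat = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    with open(path, "w") as fh:
        fh.write(delimiter.join(str(n) for n in nodes) + "\n")
        np.savetxt(fh, mat, delimiter=delimiter, fmt="%.10g")


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def binarize_to_density(w: nx.Graph, target_density: float) -> nx.Graph:
    """Keep the k strongest-weight node pairs, k = round(density·N(N-1)/2).

    Absent pairs count as weight 0. Ties at the cutoff are broken by
    lexicographic node-pair order so the result is deterministic. The
    returned graph is unweighted and keeps the full node roster.
    """
    if not (0 < target_density <= 1):
        raise ValueError("density must be in (0, 1]")
    nodes = ordered_nodes(w)
    n = len(nodes)
    if n < 2:
        raise ValueError("need at least two nodes")
    weights = {canonical_edge(u, v): float(d.get("weight", 1.0)) for u, v, d in w.edges(data=True)}
    if not any(val > 0 for val in weights.values()):
        raise ValueError("all weights are zero; nothing to binarize")
    k = _round_half_away(target_density * n * (n - 1) / 2.0)
    pairs = [
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(i + 1, n)
    ]
    pairs.sort(key=lambda p: (-weights.get(p, 0.0), node_sort_key(p[0]), node_sort_key(p[1])))
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(pairs[:k])
    return g


def consensus_network(graphs: Sequence[nx.Graph], presence_threshold: float) -> nx.Graph:
    """Group-level graph keeping edges present in ≥ threshold of inputs.

    The inclusion rule is inclusive: presence fraction exactly equal to
    the threshold keeps the edge ("at least" semantics).
    """
    if not graphs:
        raise ValueError("empty graph list")
    if not (0 < presence_threshold <= 1):
        raise ValueError("presence_threshold must be in (0, 1]")
    roster = set(graphs[0].nodes)
    for g in graphs[1:]:
        if set(g.nodes) != roster:
            raise ValueError("all graphs must share the same node set")
    counts: dict = {}
    for g in graphs:
        for u, v in g.edges:
            e = canonical_edge(u, v)
            counts[e] = counts.get(e, 0) + 1
    out = nx.Graph()
    out.add_nodes_from(roster)
    ng = len(graphs)
    out.add_edges_from(e for e, c in counts.items() if c / ng >= presence_threshold)
    return out
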