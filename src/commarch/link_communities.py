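"""Overlapping communities via link communities; the overlap score.

Edges are clustered (single-linkage, Ahn-style) by the Jaccard
similarity of the inclusive neighborhoods of their non-shared
endpoints. The dendrogram is cut at the level maximizing the partition
density

    D = (2/m) Σ_c m_c (m_c − (n_c − 1)) / ((n_c − 2)(n_c − 1))

where m_c and n_c are the edge and node counts of link community c and
the contribution of a two-node community (a single edge) is defined as
0. Each node inherits the community labels of its incident edges, so
nodes joining several link communities have multiple memberships. The
overlap score of a network is the mean number of memberships per node;
for group comparisons it is normalized by the mean overlap score of
degree-preserving random null networks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Mapping

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import linkage

from . import null_models
from ._util import canonical_edge, child_seeds, node_sort_key, ordered_edges, ordered_nodes
from .community_metrics import louvain_partition

__all__ = [
    "LinkCommunityCover",
    "OverlapResult",
    "edge_similarity",
    "link_community_cover",
    "overlap_score",
    "normalized_overlap_score",
    "maintains_segregated_structure",
]


@dataclass(frozen=True)
class LinkCommunityCover:
    """Edge partition at the partition-density-maximizing dendrogram cut."""

    edge_assignment: Mapping[tuple, int]
    node_memberships: Mapping[Hashable, frozenset]
    partition_density: float
    dendrogram: np.ndarray  # scipy linkage matrix over the canonical edge order
    edges: tuple  # canonical edge order underlying the dendrogram

    @property
    def n_communities(self) -> int:
        return len(set(self.edge_assignment.values()))


@dataclass(frozen=True)
class OverlapResult:
    overlap_score: float
    normalized_overlap: float
    n_overlapping_communities: int
    maintains_segregation: bool


def _inclusive_similarity_matrix(g: nx.Graph, nodes: list) -> np.ndarray:
    """Jaccard similarity of inclusive neighborhoods for all node pairs."""
    a = nx.to_numpy_array(g, nodelist=nodes, weight=None).astype(bool)
    np.fill_diagonal(a, True)  # inclusive: n+(x) = {x} ∪ neighbors(x)
    inter = (a.astype(np.int32) @ a.astype(np.int32).T).astype(float)
    sizes = a.sum(axis=1).astype(float)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 0.0)
    return sim


def edge_similarity(g: nx.Graph, e1: tuple, e2: tuple) -> float:
    """Similarity of two adjacent edges sharing exactly one endpoint.

    For edges (i,k) and (j,k) sharing k, returns
    |n+(i) ∩ n+(j)| / |n+(i) ∪ n+(j)| with n+(x) = {x} ∪ neighbors(x).
    """
    s1, s2 = set(e1), set(e2)
    shared = s1 & s2
    if len(shared) != 1 or s1 == s2:
        raise ValueError(f"edges {e1} and {e2} do not share exactly one node")
    (i,) = s1 - shared
    (j,) = s2 - shared
    ni = set(g.neighbors(i)) | {i}
    nj = set(g.neighbors(j)) | {j}
    return len(ni & nj) / len(ni | nj)


def _community_density_term(m_c: int, n_c: int) -> float:
    """Unnormalized partition-density contribution of one link community."""
    if n_c <= 2:
        return 0.0
    return m_c * (m_c - (n_c - 1)) / ((n_c - 2) * (n_c - 1) / 1.0)


def partition_density(g: nx.Graph, edge_assignment: Mapping[tuple, int]) -> float:
    """Direct evaluation of D on an explicit edge assignment."""
    m = g.number_of_edges()
    if m == 0:
        raise ValueError("partition density undefined without edges")
    stats: dict = {}
    for (u, v), label in edge_assignment.items():
        mc, nodes = stats.setdefault(label, [0, set()])
        stats[label][0] += 1
        nodes.update((u, v))
    total = sum(_community_density_term(mc, len(nodes)) for mc, nodes in stats.values())
    return (2.0 / m) * total


class _UnionFind:
    """Union-find over edge indices tracking community edge/node stats."""

    def __init__(self, edges):
        self.parent = list(range(len(edges)))
        self.m_c = [1] * len(edges)
        self.nodes = [set(e) for e in edges]

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return ri
        if len(self.nodes[ri]) < len(self.nodes[rj]):
            ri, rj = rj, ri  # small-to-large node-set merge
        self.parent[rj] = ri
        self.m_c[ri] += self.m_c[rj]
        self.nodes[ri].update(self.nodes[rj])
        return ri


def link_community_cover(g: nx.Graph) -> LinkCommunityCover:
    """Single-linkage link communities at the best partition-density cut.

    Non-adjacent edge pairs have similarity 0 and only merge through
    chains. Ties between cuts of equal partition density are broken
    toward fewer communities; merge ties at equal similarity follow the
    lexicographic edge order underlying the dendrogram.
    """
    m = g.number_of_edges()
    if m == 0:
        raise ValueError("link communities undefined for an edgeless graph")
    edges = ordered_edges(g)
    nodes = ordered_nodes(g)
    index = {n: i for i, n in enumerate(nodes)}

    if m == 1:
        assignment = {edges[0]: 0}
        return LinkCommunityCover(
            edge_assignment=assignment,
            node_memberships=_induced_memberships(g, assignment),
            partition_density=0.0,
            dendrogram=np.empty((0, 4)),
            edges=tuple(edges),
        )

    sim = _inclusive_similarity_matrix(g, nodes)
    # condensed distance matrix over edges: 1 - similarity for adjacent
    # pairs, exactly 1 for non-adjacent pairs
    dist = np.ones(m * (m - 1) // 2)
    edge_idx = {e: i for i, e in enumerate(edges)}
    incident: dict = {}
    for e in edges:
        for endpoint in e:
            incident.setdefault(endpoint, []).append(e)
    for k, inc in incident.items():
        for a in range(len(inc)):
            ea = inc[a]
            ia = edge_idx[ea]
            for b in range(a + 1, len(inc)):
                eb = inc[b]
                i_end = next(iter(set(ea) - {k}))
                j_end = next(iter(set(eb) - {k}))
                s = sim[index[i_end], index[j_end]]
                lo, hi = min(ia, edge_idx[eb]), max(ia, edge_idx[eb])
                pos = m * lo - lo * (lo + 1) // 2 + (hi - lo - 1)
                d = 1.0 - s
                if d < dist[pos]:
                    dist[pos] = d
    z = linkage(dist, method="single")

    # scan every dendrogram cut (between distinct merge heights), keeping
    # the maximum-D cut; >= favours later cuts, i.e. fewer communities
    uf = _UnionFind(edges)
    total = 0.0  # running sum of community density terms
    best_d, best_k = 0.0, 0  # all-singletons cut has D = 0
    cluster_root = list(range(m)) + [0] * (m - 1)  # linkage cluster id -> uf root
    heights = z[:, 2]
    for step in range(m - 1):
        i, j = int(z[step, 0]), int(z[step, 1])
        ri, rj = uf.find(cluster_root[i]), uf.find(cluster_root[j])
        total -= _community_density_term(uf.m_c[ri], len(uf.nodes[ri]))
        total -= _community_density_term(uf.m_c[rj], len(uf.nodes[rj]))
        r = uf.union(ri, rj)
        total += _community_density_term(uf.m_c[r], len(uf.nodes[r]))
        cluster_root[m + step] = r
        at_level_boundary = step == m - 2 or heights[step + 1] > heights[step]
        if at_level_boundary:
            d_here = (2.0 / m) * total
            if d_here >= best_d - 1e-12:  # ties go to the later cut: fewer communities
                best_d, best_k = max(best_d, d_here), step + 1

    # rebuild the assignment at the chosen cut
    uf = _UnionFind(edges)
    cluster_root = list(range(m)) + [0] * (m - 1)
    for step in range(best_k):
        i, j = int(z[step, 0]), int(z[step, 1])
        r = uf.union(cluster_root[i], cluster_root[j])
        cluster_root[m + step] = r
    labels: dict = {}
    assignment: dict = {}
    for i, e in enumerate(edges):
        root = uf.find(i)
        if root not in labels:
            labels[root] = len(labels)
        assignment[e] = labels[root]

    return LinkCommunityCover(
        edge_assignment=assignment,
        node_memberships=_induced_memberships(g, assignment),
        partition_density=partition_density(g, assignment),
        dendrogram=z,
        edges=tuple(edges),
    )


def _induced_memberships(g: nx.Graph, edge_assignment: Mapping[tuple, int]) -> dict:
    """Node → set of incident-edge community labels.

    Isolated nodes get one private singleton membership so that every
    node belongs to at least one community.
    """
    memberships: dict = {n: set() for n in g.nodes}
    for (u, v), label in edge_assignment.items():
        memberships[u].add(label)
        memberships[v].add(label)
    n_edge_comms = len(set(edge_assignment.values()))
    next_label = n_edge_comms
    for n in ordered_nodes(g):
        if not memberships[n]:
            memberships[n] = {next_label}
            next_label += 1
    return {n: frozenset(s) for n, s in memberships.items()}


def overlap_score(
    g: nx.Graph,
    cover: LinkCommunityCover | None = None,
    count_single_edge_communities: bool = True,
) -> float:
    """Mean number of link-community memberships per node (≥ 1).

    ``count_single_edge_communities`` is a sensitivity knob: with False,
    memberships in one-edge communities are ignored (nodes retaining no
    membership still count one, preserving the at-least-one guarantee).
    The default counts every community.
    """
    if cover is None:
        cover = link_community_cover(g)
    if count_single_edge_communities:
        counts = [len(cover.node_memberships[n]) for n in g.nodes]
    else:
        sizes: dict = {}
        for label in cover.edge_assignment.values():
            sizes[label] = sizes.get(label, 0) + 1
        multi = {lab for lab, sz in sizes.items() if sz >= 2}
        counts = [
            max(1, len([lab for lab in cover.node_memberships[n] if lab in multi]))
            for n in g.nodes
        ]
    return float(np.mean(counts))


def maintains_segregated_structure(cover: LinkCommunityCover, m_ref: int) -> bool:
    """True iff the overlapping-community count is ≥ the reference module count."""
    if m_ref < 1:
        raise ValueError("m_ref must be >= 1")
    return cover.n_communities >= m_ref


def normalized_overlap_score(
    g: nx.Graph,
    n_null: int = 10,
    seed: int = 0,
    swap_iterations_per_edge: int = 10,
    require_connected: bool = True,
    m_ref: int | None = None,
) -> OverlapResult:
    """Overlap score normalized by degree-preserving random nulls.

    The raw score is divided by the mean overlap score of ``n_null``
    degree-preserving edge-swap randomizations of ``g``. When ``m_ref``
    is not given, the reference module count for the segregated-structure
    check is the Louvain community count of ``g``.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    cover = link_community_cover(g)
    raw = overlap_score(g, cover)
    null_scores = []
    for s in child_seeds(seed, n_null):
        spec = null_models.NullSpec(
            kind="random",
            swap_iterations_per_edge=swap_iterations_per_edge,
            seed=int(s),
            require_connected=require_connected,
        )
        null_g = null_models.randomize_degree_preserving(g, spec)
        null_scores.append(overlap_score(null_g))
    if m_ref is None:
        m_ref = louvain_partition(g, seed=seed).n_communities
    return OverlapResult(
        overlap_score=raw,
        normalized_overlap=raw / float(np.mean(null_scores)),
        n_overlapping_communities=cover.n_communities,
        maintains_segregation=maintains_segregated_structure(cover, m_ref),
    )
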