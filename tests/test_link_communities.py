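import networkx as nx
import numpy as np
import pytest

from commarch import link_communities as lc
from commarch.community_metrics import louvain_partition
from commarch.synthetic_networks import ModularSpec, generate_er, generate_modular

from .oracles import best_cut_density, direct_partition_density


class TestEdgeSimilarity:
    def test_bare_path(self):
        g = nx.path_graph(["i", "k", "j"])
        assert lc.edge_similarity(g, ("i", "k"), ("k", "j")) == pytest.approx(1 / 3)

    def test_triangle_edges_identical_neighborhoods(self):
        g = nx.complete_graph(["i", "j", "k"])
        assert lc.edge_similarity(g, ("i", "k"), ("j", "k")) == pytest.approx(1.0)

    def test_bowtie_bridge_vs_triangle_edge(self, bowtie):
        assert lc.edge_similarity(bowtie, ("c", "d"), ("a", "c")) == pytest.approx(1 / 6)

    def test_non_adjacent_pair_errors(self, bowtie):
        with pytest.raises(ValueError):
            lc.edge_similarity(bowtie, ("a", "b"), ("e", "f"))


class TestLinkCommunityCover:
    def test_k4_single_community_full_density(self):
        cover = lc.link_community_cover(nx.complete_graph(4))
        assert cover.n_communities == 1
        assert cover.partition_density == pytest.approx(1.0)

    def test_two_disjoint_k4(self):
        cover = lc.link_community_cover(nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4)))
        assert cover.n_communities == 2
        assert cover.partition_density == pytest.approx(1.0)

    def test_bowtie_three_communities(self, bowtie):
        cover = lc.link_community_cover(bowtie)
        assert cover.n_communities == 3
        labels = {cover.edge_assignment[e] for e in [("a", "b"), ("a", "c"), ("b", "c")]}
        assert len(labels) == 1  # first triangle is one community
        assert cover.edge_assignment[("c", "d")] not in labels  # bridge is its own

    def test_edgeless_graph_errors(self):
        g = nx.Graph()
        g.add_nodes_from(range(3))
        with pytest.raises(ValueError):
            lc.link_community_cover(g)

    def test_partition_density_matches_direct_evaluation(self, small_fixture_set):
        for name, g in small_fixture_set.items():
            cover = lc.link_community_cover(g)
            direct = direct_partition_density(g, dict(cover.edge_assignment))
            assert cover.partition_density == pytest.approx(direct, abs=1e-12), name

    def test_returned_cut_is_optimal_over_all_cuts(self, small_fixture_set):
        # exhaustive rescan of every dendrogram threshold (fixtures m <= 15)
        for name, g in small_fixture_set.items():
            cover = lc.link_community_cover(g)
            oracle = best_cut_density(g, cover.dendrogram, list(cover.edges))
            assert cover.partition_density == pytest.approx(oracle, abs=1e-9), name

    def test_membership_counts_consistent(self, small_fixture_set):
        # sum of per-node membership counts equals sum of community node counts
        for name, g in small_fixture_set.items():
            cover = lc.link_community_cover(g)
            comm_nodes: dict = {}
            for (u, v), lab in cover.edge_assignment.items():
                comm_nodes.setdefault(lab, set()).update((u, v))
            total = sum(len(s) for s in comm_nodes.values())
            assert sum(len(m) for m in cover.node_memberships.values()) == total, name


class TestOverlapScore:
    def test_single_community_graphs_score_one(self):
        assert lc.overlap_score(nx.complete_graph(4)) == pytest.approx(1.0)
        assert lc.overlap_score(
            nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        ) == pytest.approx(1.0)

    def test_bowtie_score(self, bowtie):
        # bridge endpoints have 2 memberships each: (1+1+2+2+1+1)/6
        assert lc.overlap_score(bowtie) == pytest.approx(4 / 3)

    def test_relabeling_invariance(self, bowtie):
        relabeled = nx.relabel_nodes(bowtie, dict(zip("abcdef", "uvwxyz")))
        assert lc.overlap_score(relabeled) == pytest.approx(lc.overlap_score(bowtie))

    def test_isolated_node_counts_one_membership(self, bowtie):
        g = bowtie.copy()
        g.add_node("zzz")
        cover = lc.link_community_cover(g)
        assert len(cover.node_memberships["zzz"]) == 1
        assert lc.overlap_score(g, cover) == pytest.approx((4 / 3 * 6 + 1) / 7)


class TestMaintainsSegregation:
    def test_inclusive_threshold(self):
        cover_stub = lc.link_community_cover(nx.complete_graph(4))
        assert lc.maintains_segregated_structure(cover_stub, 1)
        assert not lc.maintains_segregated_structure(cover_stub, 2)

    def test_bowtie_vs_louvain_reference(self, bowtie):
        cover = lc.link_community_cover(bowtie)
        m_ref = louvain_partition(bowtie, seed=0).n_communities
        assert m_ref == 2
        assert lc.maintains_segregated_structure(cover, m_ref)  # 3 >= 2


class TestNormalizedOverlap:
    def test_identity_null_gives_exactly_one(self, bowtie):
        res = lc.normalized_overlap_score(bowtie, n_null=1, seed=0, swap_iterations_per_edge=0)
        assert res.normalized_overlap == pytest.approx(1.0)

    def test_er_self_null_near_one(self):
        # an already-random graph is indistinguishable from its own nulls
        # (brain-scale ER: N=164, mean degree 16)
        vals = []
        for s in range(5):
            g = generate_er(164, 16, seed=s)
            vals.append(lc.normalized_overlap_score(g, n_null=5, seed=100 + s).normalized_overlap)
        assert 0.9 <= float(np.mean(vals)) <= 1.1

    def test_planted_partition_above_one(self):
        g = generate_modular(ModularSpec(N=80, M=4, p_in=0.6, p_out=0.05, seed=3))
        res = lc.normalized_overlap_score(g, n_null=5, seed=4)
        assert res.normalized_overlap > 1.0
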