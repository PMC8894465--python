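import networkx as nx
import numpy as np
import pytest


@pytest.fixture
def bowtie():
    """Two triangles joined by one bridge edge (6 nodes, 7 edges)."""
    return nx.Graph(
        [("a", "b"), ("a", "c"), ("b", "c"), ("c", "d"), ("d", "e"), ("d", "f"), ("e", "f")]
    )


@pytest.fixture
def two_k5():
    return nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))


@pytest.fixture(scope="session")
def atlas_connected_6():
    """All connected graphs with 2..6 nodes and >= 1 edge (graph atlas)."""
    graphs = [
        g
        for g in nx.graph_atlas_g()
        if 2 <= g.number_of_nodes() <= 6 and g.number_of_edges() >= 1 and nx.is_connected(g)
    ]
    assert len(graphs) == 142  # 1 + 2 + 6 + 21 + 112
    return graphs


@pytest.fixture(scope="session")
def atlas_connected_7_sample():
    """Seeded sample of connected 7-node atlas graphs."""
    sevens = [
        g
        for g in nx.graph_atlas_g()
        if g.number_of_nodes() == 7 and g.number_of_edges() >= 1 and nx.is_connected(g)
    ]
    rng = np.random.default_rng(20240901)
    idx = rng.choice(len(sevens), size=40, replace=False)
    return [sevens[i] for i in idx]


@pytest.fixture(scope="session")
def small_fixture_set():
    """Named small graphs used across oracle tests."""
    bowtie = nx.Graph(
        [("a", "b"), ("a", "c"), ("b", "c"), ("c", "d"), ("d", "e"), ("d", "f"), ("e", "f")]
    )
    return {
        "bowtie": bowtie,
        "k4": nx.complete_graph(4),
        "two_k4": nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4)),
        "path5": nx.path_graph(5),
        "star6": nx.star_graph(5),
        "cycle6": nx.cycle_graph(6),
        "barbell": nx.barbell_graph(4, 1),
        "petersen": nx.petersen_graph(),
    }
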