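import numpy as np
import pytest

from volnet import BrainGraph, bundled_roster


def graph_from_edges(n, edges, prefix="v"):
    labels = [f"{prefix}{i}_l" for i in range(n)]
    return BrainGraph.from_edges(labels, [(labels[a], labels[b]) for a, b in edges])


@pytest.fixture(scope="session")
def roster82():
    return bundled_roster()


@pytest.fixture
def triangle():
    return graph_from_edges(3, [(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def path3():
    """Path a-b-c."""
    return graph_from_edges(3, [(0, 1), (1, 2)])


@pytest.fixture
def k4():
    return graph_from_edges(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])


@pytest.fixture
def k5():
    return graph_from_edges(5, [(i, j) for i in range(5) for j in range(i + 1, 5)])


@pytest.fixture
def star4():
    """Star K1,4 with center v0."""
    return graph_from_edges(5, [(0, i) for i in range(1, 5)])


@pytest.fixture
def two_cliques_bridge():
    """Two K4 cliques joined by a single bridge edge."""
    edges = [(i, j) for i in range(4) for j in range(i + 1, 4)]
    edges += [(i + 4, j + 4) for i, j in edges[:6]]
    edges += [(0, 4)]
    return graph_from_edges(8, edges)


def to_networkx(graph):
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(graph.labels)
    g.add_edges_from(graph.edges())
    return g


def to_igraph(graph):
    import igraph as ig

    idx = {lab: i for i, lab in enumerate(graph.labels)}
    g = ig.Graph(
        n=graph.n_nodes,
        edges=[(idx[a], idx[b]) for a, b in graph.edges()],
        directed=False,
    )
    g.vs["name"] = list(graph.labels)
    return g
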