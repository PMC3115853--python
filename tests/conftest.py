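import networkx as nx
import pytest

from netcentral.graph import Graph


def graph_from_nx(g: nx.Graph) -> Graph:
    """Convert a networkx graph, preserving node order via sorted labels."""
    nodes = [str(v) for v in sorted(g.nodes())]
    edges = [(str(u), str(v)) for u, v in g.edges()]
    return Graph.from_edges(edges, nodes=nodes)


def er_graph(n: int, p: float, seed: int) -> Graph:
    return graph_from_nx(nx.gnp_random_graph(n, p, seed=seed))


@pytest.fixture
def path3() -> Graph:
    return Graph.from_edges([("a", "b"), ("b", "c")])


@pytest.fixture
def star4() -> Graph:
    """Center 'c' plus three leaves; center is node index 0."""
    return Graph.from_edges([("c", "x"), ("c", "y"), ("c", "z")])


@pytest.fixture
def cycle4() -> Graph:
    return Graph.from_edges([("0", "1"), ("1", "2"), ("2", "3"), ("3", "0")])


@pytest.fixture
def k4() -> Graph:
    labels = ["a", "b", "c", "d"]
    return Graph.from_edges(
        [(labels[i], labels[j]) for i in range(4) for j in range(i + 1, 4)]
    )


@pytest.fixture
def disjoint_edges() -> Graph:
    return Graph.from_edges([("a", "b"), ("c", "d")])
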