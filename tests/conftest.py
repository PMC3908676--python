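import networkx as nx
import pytest


def labelled(g: nx.Graph) -> nx.Graph:
    """Relabel integer nodes to strings ('n00', 'n01', ...) for ID-based tie-breaks."""
    return nx.relabel_nodes(g, {v: f"n{v:02d}" for v in g.nodes})


@pytest.fixture
def triangle() -> nx.Graph:
    return nx.Graph([("a", "b"), ("b", "c"), ("c", "a")])


@pytest.fixture
def k4() -> nx.Graph:
    return labelled(nx.complete_graph(4))


@pytest.fixture
def star5() -> nx.Graph:
    """Star: centre n00 with 4 leaves."""
    return labelled(nx.star_graph(4))


@pytest.fixture
def two_k4() -> nx.Graph:
    """Two disjoint 4-cliques."""
    g = labelled(nx.complete_graph(4))
    h = nx.relabel_nodes(nx.complete_graph(4), {v: f"m{v:02d}" for v in range(4)})
    return nx.compose(g, h)
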