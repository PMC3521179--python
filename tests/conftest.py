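import networkx as nx
import pytest

from complexkit.network import IntegratedNetwork


def make_network(edges, sources=None, isolated=()):
    """Build an IntegratedNetwork from (a, b) pairs, optionally per-edge tags."""
    net = IntegratedNetwork()
    for i, (a, b) in enumerate(edges):
        tag = sources[i] if sources else "X"
        if isinstance(tag, (list, tuple, set)):
            for t in tag:
                net.add_interaction(a, b, t)
        else:
            net.add_interaction(a, b, tag)
    for node in isolated:
        net.add_protein(node)
    return net


def clique_edges(nodes):
    nodes = list(nodes)
    return [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1 :]]


@pytest.fixture
def two_cliques_net():
    """Two disjoint 4-cliques."""
    return make_network(clique_edges("ABCD") + clique_edges("WXYZ"))


@pytest.fixture
def triangle_graph():
    g = nx.Graph()
    g.add_edges_from(clique_edges("ABC"))
    return g
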