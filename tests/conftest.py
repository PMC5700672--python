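import networkx as nx
import pytest

from diffcentral import SampleInstance, build_instance_set


@pytest.fixture
def path_graph():
    return nx.Graph([("A", "B"), ("B", "C")])


@pytest.fixture
def star_graph():
    g = nx.Graph()
    g.add_edges_from(("hub", f"leaf{i}") for i in range(4))
    return g


@pytest.fixture
def tiny_interactome():
    """Seven genes: a hub (g1) with spokes, a triangle, one isolated gene."""
    g = nx.Graph()
    g.add_edges_from([
        ("g1", "g2"), ("g1", "g3"), ("g1", "g4"),
        ("g4", "g5"), ("g5", "g6"), ("g4", "g6"),
    ])
    g.add_node("g7")
    return g


@pytest.fixture
def identity_pairs(tiny_interactome):
    """Three instances whose normal and tumor graphs coincide."""
    genes = set(tiny_interactome.nodes)
    instances = [
        SampleInstance(f"I{i}", set(genes), set(genes), set()) for i in range(3)
    ]
    return build_instance_set(tiny_interactome, instances)


def random_graph(rng, n_min=2, n_max=8, p=0.4):
    """Small Erdos-Renyi graph with string node labels."""
    n = rng.randint(n_min, n_max)
    g = nx.Graph()
    g.add_nodes_from(f"n{i}" for i in range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(f"n{i}", f"n{j}")
    return g
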