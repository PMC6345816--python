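import networkx as nx
import numpy as np
import pytest

from multidom.netcore import MultilayerNetwork, new_graph


def er_graph(n: int, p: float, seed: int) -> nx.Graph:
    """Erdős–Rényi-style random graph with zero-padded string labels."""
    g = nx.gnp_random_graph(n, p, seed=seed)
    return nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})


def random_two_layer(n: int, p: float, seed: int) -> MultilayerNetwork:
    rng = np.random.default_rng(seed)
    return MultilayerNetwork(
        [er_graph(n, p, int(rng.integers(2**31))) for _ in range(2)]
    )


@pytest.fixture
def path4():
    return new_graph("abcd", [("a", "b"), ("b", "c"), ("c", "d")])


@pytest.fixture
def star5():
    """Star with centre x and leaves p, q, r, s."""
    return new_graph("xpqrs", [("x", v) for v in "pqrs"])


@pytest.fixture
def cycle6():
    nodes = [f"c{i}" for i in range(6)]
    return new_graph(nodes, list(zip(nodes, nodes[1:] + nodes[:1])))
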