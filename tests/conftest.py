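import networkx as nx
import numpy as np
import pytest

from netprio import (
    SyntheticConfig,
    WeightedNetwork,
    generate_instance,
    load_network,
)


def make_random_network(
    n: int, rng: np.random.Generator, p: float = 0.15
) -> WeightedNetwork:
    """Largest connected component of a G(n, p) graph with uniform
    weights in (0.1, 1]."""
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    giant = max(nx.connected_components(g), key=len)
    graph = nx.Graph()
    width = len(str(n))
    for u, v in g.subgraph(giant).edges():
        graph.add_edge(
            f"G{u:0{width}d}",
            f"G{v:0{width}d}",
            weight=float(rng.uniform(0.1, 1.0)),
        )
    return WeightedNetwork(graph)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def triangle():
    return load_network([("A", "B", 1.0), ("B", "C", 1.0), ("A", "C", 1.0)])


@pytest.fixture
def path3():
    return load_network([("A", "B", 1.0), ("B", "C", 1.0)])


@pytest.fixture
def star():
    return load_network(
        [("HUB", "L1", 0.5), ("HUB", "L2", 0.5), ("HUB", "L3", 0.5)]
    )


@pytest.fixture
def random_net(rng):
    return make_random_network(50, rng)


@pytest.fixture(scope="session")
def small_instance():
    """A 200-gene synthetic benchmark shared by evaluation tests."""
    return generate_instance(
        SyntheticConfig(n_nodes=200, n_diseases=8), rng=42
    )
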