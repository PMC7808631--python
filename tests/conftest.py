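import networkx as nx
import numpy as np
import pytest

from labelrank import ContactNetwork
from labelrank.epidemic import Observation, ObservationMode, ObservedState

I, S, U = ObservedState.INFECTED, ObservedState.UNINFECTED, ObservedState.UNKNOWN


def obs_from(codes, mode=ObservationMode.COMPLETE) -> Observation:
    """Build an Observation from a sequence of ObservedState codes."""
    return Observation(values=np.array(codes, dtype=np.int8), mode=mode)


def random_connected_graph(rng: np.random.Generator, n_max: int = 30) -> ContactNetwork:
    """A small random connected graph (spanning tree + extra edges)."""
    n = int(rng.integers(3, n_max + 1))
    g = nx.random_labeled_tree(n, seed=int(rng.integers(2**31)))
    extra = int(rng.integers(0, n))
    for _ in range(extra):
        u, v = rng.integers(n, size=2)
        if u != v:
            g.add_edge(int(u), int(v))
    return ContactNetwork(g)


@pytest.fixture
def p3():
    return ContactNetwork(nx.path_graph(3))


@pytest.fixture
def p5():
    return ContactNetwork(nx.path_graph(5))


@pytest.fixture
def p10():
    return ContactNetwork(nx.path_graph(10))


@pytest.fixture
def k3():
    return ContactNetwork(nx.complete_graph(3))


@pytest.fixture
def k5():
    return ContactNetwork(nx.complete_graph(5))


@pytest.fixture
def star5():
    """Star on 5 nodes: center 0, leaves 1..4."""
    return ContactNetwork(nx.star_graph(4))


@pytest.fixture(scope="session")
def ws200():
    from labelrank import generate_ws

    return generate_ws(200, 12, 0.2, seed=7)


@pytest.fixture(scope="session")
def ba200():
    from labelrank import generate_ba

    return generate_ba(200, 6, seed=7)
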