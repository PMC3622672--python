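"""Shared fixtures: tiny hand-checkable graphs and a small synthetic bundle."""

import numpy as np
import pytest

from diffprio import (
    GeneNetwork,
    SyntheticConfig,
    build_transition_matrix,
    generate_bundle,
)


@pytest.fixture
def path_network():
    """Single edge a--b."""
    return GeneNetwork(edges=[("a", "b")])


@pytest.fixture
def triangle_network():
    return GeneNetwork(edges=[("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def star_network():
    """Center c with leaves x, y, z."""
    return GeneNetwork(edges=[("c", "x"), ("c", "y"), ("c", "z")])


@pytest.fixture
def cycle_network():
    """6-cycle n0-n1-...-n5-n0 (2-regular, vertex-transitive)."""
    nodes = [f"n{i}" for i in range(6)]
    return GeneNetwork(edges=[(nodes[i], nodes[(i + 1) % 6]) for i in range(6)])


@pytest.fixture
def path5_network():
    """Path a-b-c-d-e, used for disease-walk fixtures."""
    return GeneNetwork(edges=[("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")])


@pytest.fixture
def transition(path_network):
    return build_transition_matrix(path_network)


def random_connected_network(rng, n_max=50):
    """A random graph with no isolated node, for oracle-equivalence tests."""
    import networkx as nx

    n = int(rng.integers(4, n_max + 1))
    if rng.random() < 0.5:
        g = nx.gnp_random_graph(n, float(rng.uniform(0.1, 0.4)),
                                seed=int(rng.integers(2**31 - 1)))
    else:
        g = nx.barabasi_albert_graph(n, int(rng.integers(1, 4)),
                                     seed=int(rng.integers(2**31 - 1)))
    # attach isolated nodes so every column of M is stochastic
    isolated = [v for v in g.nodes if g.degree[v] == 0]
    others = [v for v in g.nodes if g.degree[v] > 0]
    for v in isolated:
        g.add_edge(v, others[int(rng.integers(len(others)))] if others else (v + 1) % n)
    return GeneNetwork(edges=[(f"g{a:03d}", f"g{b:03d}") for a, b in g.edges])


@pytest.fixture(scope="session")
def small_bundle():
    """Planted-structure bundle small enough for fast end-to-end runs."""
    return generate_bundle(
        SyntheticConfig(n_genes=80, n_diseases=8, seed=7,
                        cluster_pool_size=10)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
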