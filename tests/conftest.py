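import numpy as np
import pytest
import scipy.sparse as sp

from qwprio import PPINetwork, SeedSet, benchmark_suite
from qwprio.synthetic import SMALL_FIXTURE


@pytest.fixture
def single_edge():
    return PPINetwork.from_edges([("A", "B")])


@pytest.fixture
def triangle():
    return PPINetwork.from_edges([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def star4():
    """Hub H with three leaves."""
    return PPINetwork.from_edges([("H", "L1"), ("H", "L2"), ("H", "L3")])


@pytest.fixture
def path3():
    return PPINetwork.from_edges([("A", "B"), ("B", "C")])


@pytest.fixture
def edgeless3():
    return PPINetwork(["A", "B", "C"], sp.csr_matrix((3, 3)))


def random_network(n, kind, rng):
    """ER or preferential-attachment test network with generic gene ids."""
    import networkx as nx

    if kind == "er":
        g = nx.gnp_random_graph(n, 4.0 / n, seed=int(rng.integers(2**31)))
    else:
        g = nx.barabasi_albert_graph(n, 2, seed=int(rng.integers(2**31)))
    ids = [f"G{i:04d}" for i in range(n)]
    edges = [(ids[a], ids[b]) for a, b in g.edges()] or [(ids[0], ids[1])]
    return PPINetwork.from_edges(edges, node_order=ids)


def random_seed_set(net, size, rng, disease_id="d"):
    idx = rng.choice(net.n, size=size, replace=False)
    return SeedSet(disease_id, frozenset(int(i) for i in idx), net.n)


@pytest.fixture(scope="session")
def small_bench():
    """The fixed small benchmark: one n=200 network, 5 planted diseases."""
    return benchmark_suite([SMALL_FIXTURE], n_diseases=5)[0]
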