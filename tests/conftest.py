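import networkx as nx
import numpy as np
import pytest


@pytest.fixture
def path_graph():
    """The 3-node path A-B-C."""
    return nx.Graph([("A", "B"), ("B", "C")])


@pytest.fixture(scope="session")
def toy_ppi():
    from m6adriver import generate_toy_ppi

    return generate_toy_ppi(100, rng_seed=7)


@pytest.fixture(scope="session")
def toy_null_model(toy_ppi):
    """A small null model on the session toy network, reused across tests."""
    from m6adriver import RandomizationConfig, build_null_model

    return build_null_model(toy_ppi, RandomizationConfig(n_networks=10, rng_seed=11))


def rwr_exact(graph: nx.Graph, seeds: set[str], restart_prob: float) -> dict[str, float]:
    """Independent closed-form stationary solution p* = lam (I - (1-lam)M)^-1 p0.

    Builds the column-normalized adjacency densely from the graph, bypassing
    the package's transition-matrix and iteration code entirely.
    """
    nodes = sorted(graph.nodes())
    n = len(nodes)
    idx = {node: i for i, node in enumerate(nodes)}
    A = np.zeros((n, n))
    for u, v in graph.edges():
        A[idx[u], idx[v]] = 1.0
        A[idx[v], idx[u]] = 1.0
    M = A / A.sum(axis=0, keepdims=True)
    p0 = np.zeros(n)
    for s in seeds:
        p0[idx[s]] = 1.0 / len(seeds)
    p = restart_prob * np.linalg.solve(np.eye(n) - (1 - restart_prob) * M, p0)
    return dict(zip(nodes, p))
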