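import numpy as np
import pytest

from grwnet.model import ModelParams, generate_network, kappa_law_mean
from grwnet.network import NodeTable, WeightedNetwork


@pytest.fixture(scope="session")
def medium_ws1():
    """One calibrated WS1 network (n=1024, τ=0.5) shared across tests."""
    params = ModelParams(n_nodes=1024, seed=12345, tau=0.5, eta=0.9)
    target = kappa_law_mean(params.kappa_law, params.n_nodes)
    net, nodes, fitted = generate_network(params, target_mean_degree=target)
    return net, nodes, fitted


@pytest.fixture
def toy_network():
    """5-node weighted path-plus-chord used for hand-checkable statistics."""
    edges = np.array([[0, 1], [1, 2], [2, 3], [3, 4], [0, 2]])
    weights = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    return WeightedNetwork(5, edges, weights)


@pytest.fixture
def two_triangles():
    """Two triangles joined by a single bridge edge (7 edges in total)."""
    edges = np.array([[0, 1], [1, 2], [0, 2], [3, 4], [4, 5], [3, 5], [2, 3]])
    return WeightedNetwork(6, edges, np.ones(7))


def ring_nodes(n: int, kappa: float = 10.0) -> NodeTable:
    """Evenly spaced angles, constant hidden degree — fully deterministic geometry."""
    theta = np.arange(n) * 2.0 * np.pi / n
    return NodeTable(theta=theta, kappa=np.full(n, kappa), sigma=np.full(n, kappa))
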