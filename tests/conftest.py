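import numpy as np
import pytest

from plastnet import ConnectivityMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_symmetric_matrix(n, rng, signed=False):
    A = rng.uniform(-1 if signed else 0, 1, size=(n, n))
    W = (A + A.T) / 2
    np.fill_diagonal(W, 1.0)
    return ConnectivityMatrix(W, [f"n{i}" for i in range(n)])


@pytest.fixture
def two_cliques():
    """Two disconnected 4-cliques with unit weights."""
    W = np.zeros((8, 8))
    W[:4, :4] = 1.0
    W[4:, 4:] = 1.0
    np.fill_diagonal(W, 1.0)
    return ConnectivityMatrix(W, [f"n{i}" for i in range(8)])
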