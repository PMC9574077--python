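import numpy as np
import pytest

from healthdea.spatial import build_weights
from healthdea.synthetic import china_adjacency


def rook_pairs(side: int):
    """Contiguity pairs of a side x side rook grid, units 0..side^2-1."""
    pairs = []
    for i in range(side):
        for j in range(side):
            u = i * side + j
            if j < side - 1:
                pairs.append((u, u + 1))
            if i < side - 1:
                pairs.append((u, u + side))
    return pairs


def rook_weights(side: int, standardize: bool = True):
    return build_weights(rook_pairs(side), list(range(side * side)),
                         standardize=standardize)


@pytest.fixture(scope="session")
def grid5():
    return rook_weights(5)


@pytest.fixture(scope="session")
def grid7():
    return rook_weights(7)


@pytest.fixture(scope="session")
def china_weights():
    units = sorted({u for p in china_adjacency() for u in p})
    return build_weights(china_adjacency(), units)


@pytest.fixture
def chain_instance():
    """Single input/intermediate/output chain: A(1,2,4), B(1,1,1), C(2,2,2)."""
    X = np.array([[1.0], [1.0], [2.0]])
    Z = np.array([[2.0], [1.0], [2.0]])
    Y = np.array([[4.0], [1.0], [2.0]])
    return X, Z, Y
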