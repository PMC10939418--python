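import numpy as np
import pytest
import scipy.sparse as sp

from sgae.graph import SpatialGraph, build_knn_graph
from sgae.io import CoordinateTable
from sgae.simulate import make_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def tiny_dataset():
    return make_fixture("tiny")


@pytest.fixture(scope="session")
def tiny_graph(tiny_dataset):
    return build_knn_graph(tiny_dataset.coords, k=4)


def random_graph(rng, n: int, p: float = 0.3) -> SpatialGraph:
    """Random symmetric binary graph (Erdős–Rényi), possibly with isolates."""
    a = rng.random((n, n)) < p
    a = np.triu(a, 1)
    a = a | a.T
    return SpatialGraph(sp.csr_matrix(a.astype(float)))


def random_coords(rng, n: int) -> CoordinateTable:
    return CoordinateTable(rng.random((n, 2)) * 10, [f"s{i}" for i in range(n)])
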