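import numpy as np
import pytest

from gmaps import Graph, GraphDataset, degree_onehot


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_graph(n: int, f: int, rng: np.random.Generator, p: float = 0.5) -> Graph:
    """Random symmetric graph with gaussian features (test helper)."""
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, k=1).astype(float)
    adj = adj + adj.T
    return Graph(adj, rng.normal(size=(n, f)), label=int(rng.integers(0, 2)))


@pytest.fixture
def small_graph(rng):
    return random_graph(6, 4, rng)


@pytest.fixture
def tiny_dataset(rng):
    """12 featureless graphs in 2 classes: triangles vs 4-stars."""
    graphs = []
    tri = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
    star = np.zeros((5, 5))
    star[0, 1:] = 1.0
    star[1:, 0] = 1.0
    for i in range(6):
        graphs.append(Graph(tri, np.zeros((3, 0)), 0))
        graphs.append(Graph(star, np.zeros((5, 0)), 1))
    return degree_onehot(GraphDataset(graphs, 2))


@pytest.fixture
def permutation(rng):
    def _make(n):
        p = rng.permutation(n)
        mat = np.zeros((n, n))
        mat[np.arange(n), p] = 1.0
        return p, mat
    return _make
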