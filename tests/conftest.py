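import numpy as np
import pytest
import scipy.sparse as sp

from icdgraph.graph import Graph, PropagationOperator


def make_graph(adj, d=3, C=2, seed=0, labels=None):
    """Graph from a dense adjacency with random features and labels."""
    rng = np.random.default_rng(seed)
    adj = np.asarray(adj, dtype=float)
    n = adj.shape[0]
    X = rng.normal(size=(n, d))
    if labels is None:
        labels = np.zeros((n, C), dtype=int)
        labels[np.arange(n), rng.integers(0, C, n)] = 1
    return Graph(adjacency=sp.csr_matrix(adj), features=X, labels=labels)


@pytest.fixture
def path3():
    """3-node path graph 0-1-2."""
    A = np.zeros((3, 3))
    A[0, 1] = A[1, 0] = A[1, 2] = A[2, 1] = 1
    return make_graph(A)


@pytest.fixture
def pair_graph():
    """Two nodes joined by one edge."""
    return make_graph([[0, 1], [1, 0]])


@pytest.fixture
def single_node():
    return make_graph(np.zeros((1, 1)))


@pytest.fixture
def er_graph():
    """Erdos-Renyi graph used across tests (n=20, p=0.2, fixed seed)."""
    rng = np.random.default_rng(42)
    n = 20
    A = np.triu((rng.random((n, n)) < 0.2).astype(float), k=1)
    return make_graph(A + A.T, d=4, C=3, seed=1)


def two_node_bar_op():
    """Operator with A_bar = [[0.75, 0.25], [0.25, 0.75]] (the worked case)."""
    A_hat = sp.csr_matrix(np.full((2, 2), 0.5))
    op = PropagationOperator(strategy="M2", A_hat=A_hat, K=1)
    op.A_bar = np.array([[0.75, 0.25], [0.25, 0.75]])
    return op
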