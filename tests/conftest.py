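import numpy as np
import pytest

from structconn import ThresholdedGraph


def graph_from_edges(n, edges):
    A = np.zeros((n, n), dtype=np.int8)
    for i, j in edges:
        A[i, j] = A[j, i] = 1
    return ThresholdedGraph(
        region_names=[f"R{k}" for k in range(n)],
        adjacency=A,
        target_density=A.sum() / (n * (n - 1)) if n > 1 else 0.0,
    )


def random_graph(n, p, rng):
    """Erdos-Renyi graph with at least one edge."""
    while True:
        A = (rng.random((n, n)) < p).astype(np.int8)
        A = np.triu(A, 1)
        A = A + A.T
        if A.sum() > 0:
            return ThresholdedGraph(
                region_names=[f"R{k}" for k in range(n)],
                adjacency=A,
                target_density=A.sum() / (n * (n - 1)),
            )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def two_triangles():
    return graph_from_edges(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])


@pytest.fixture
def path3():
    return graph_from_edges(3, [(0, 1), (1, 2)])


@pytest.fixture
def complete5():
    return graph_from_edges(5, [(i, j) for i in range(5) for j in range(i + 1, 5)])
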