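import numpy as np
import pytest

from mouseconn.types import RoiTimeSeries, WeightedGraph


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def triangle():
    w = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
    return WeightedGraph(node_names=["a", "b", "c"], weights=w)


@pytest.fixture()
def two_cliques():
    """Two disconnected unit-weight 5-cliques."""
    n = 10
    w = np.zeros((n, n))
    for block in (range(5), range(5, 10)):
        for i in block:
            for j in block:
                if i != j:
                    w[i, j] = 1.0
    return WeightedGraph(node_names=[f"n{i}" for i in range(n)], weights=w)


@pytest.fixture()
def small_series(rng):
    """A well-behaved 6-node, 120-frame series with no censoring."""
    data = rng.standard_normal((6, 120))
    return RoiTimeSeries(subject_id="s1", group="placebo", session="chronic",
                         node_names=[f"r{i}" for i in range(6)], data=data)


def ring_lattice(n: int = 100, k: int = 6, shortcut_frac: float = 0.05,
                 seed: int = 0) -> WeightedGraph:
    """Ring lattice (k nearest neighbours) with a fraction of random
    shortcut rewirings, unit weights."""
    rng = np.random.default_rng(seed)
    w = np.zeros((n, n))
    for i in range(n):
        for step in range(1, k // 2 + 1):
            j = (i + step) % n
            w[i, j] = w[j, i] = 1.0
    edges = [(i, j) for i in range(n) for j in range(i + 1, n) if w[i, j]]
    n_rewire = int(round(shortcut_frac * len(edges)))
    chosen = rng.choice(len(edges), size=n_rewire, replace=False)
    for idx in chosen:
        i, j = edges[idx]
        for _ in range(50):
            a, b = rng.integers(0, n, size=2)
            if a != b and w[a, b] == 0 and (a, b) != (i, j):
                w[i, j] = w[j, i] = 0.0
                w[a, b] = w[b, a] = 1.0
                break
    return WeightedGraph(node_names=[str(i) for i in range(n)], weights=w)
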