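"""Independent brute-force reference implementations used only by tests.

Everything here is written directly from the defining formulas with plain
Python loops (or a textbook all-pairs algorithm), deliberately sharing no
code with the package, so that agreement between the two routes is
meaningful evidence of correctness on small graphs.
"""

from __future__ import annotations

import numpy as np


def brute_strength(w: np.ndarray) -> np.ndarray:
    n = len(w)
    return np.array([sum(w[i][j] for j in range(n)) for i in range(n)])


def brute_clustering(w: np.ndarray) -> np.ndarray:
    """Geometric-mean weighted clustering on max-normalized weights."""
    n = len(w)
    wmax = w.max()
    wn = w / wmax if wmax > 0 else w
    out = np.zeros(n)
    for i in range(n):
        k = sum(1 for j in range(n) if w[i][j] > 0)
        if k < 2:
            continue
        tri = 0.0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h:
                    tri += (wn[i][j] * wn[i][h] * wn[j][h]) ** (1.0 / 3.0)
        out[i] = tri / (k * (k - 1))
    return out


def brute_transitivity(w: np.ndarray) -> float:
    n = len(w)
    wmax = w.max()
    wn = w / wmax if wmax > 0 else w
    tri = 0.0
    triplets = 0.0
    for i in range(n):
        k = sum(1 for j in range(n) if w[i][j] > 0)
        triplets += k * (k - 1)
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h:
                    tri += (wn[i][j] * wn[i][h] * wn[j][h]) ** (1.0 / 3.0)
    return tri / triplets if triplets > 0 else 0.0


def floyd_warshall(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths on lengths 1/weight."""
    n = len(w)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and w[i][j] > 0:
                d[i][j] = 1.0 / w[i][j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return d


def brute_cpl(w: np.ndarray) -> float:
    d = floyd_warshall(w)
    vals = [d[i][j] for i in range(len(w)) for j in range(len(w))
            if i != j and np.isfinite(d[i][j])]
    return float(np.mean(vals))


def brute_efficiency(w: np.ndarray) -> float:
    d = floyd_warshall(w)
    n = len(w)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i][j]) and d[i][j] > 0:
                total += 1.0 / d[i][j]
    return total / (n * (n - 1)) if n > 1 else 0.0


def brute_betweenness(w: np.ndarray) -> np.ndarray:
    """Betweenness by enumerating all shortest paths between every pair."""
    n = len(w)
    d = floyd_warshall(w)
    # count shortest paths and per-node pass-through fractions
    out = np.zeros(n)
    for s in range(n):
        for t in range(n):
            if s >= t or not np.isfinite(d[s][t]) or s == t:
                continue
            paths = _all_shortest_paths(w, d, s, t)
            sigma = len(paths)
            for v in range(n):
                if v == s or v == t:
                    continue
                through = sum(1 for p in paths if v in p[1:-1])
                out[v] += through / sigma
    return out


def _all_shortest_paths(w, d, s, t, tol=1e-12):
    """Enumerate node sequences realizing d[s][t] (small graphs only)."""
    paths = []

    def extend(path, length):
        v = path[-1]
        if v == t and abs(length - d[s][t]) < tol:
            paths.append(list(path))
            return
        for u in range(len(w)):
            if w[v][u] > 0 and u not in path:
                step = 1.0 / w[v][u]
                if length + step + d[u][t] <= d[s][t] + tol:
                    path.append(u)
                    extend(path, length + step)
                    path.pop()

    extend([s], 0.0)
    return paths


def brute_assortativity(w: np.ndarray) -> float:
    """Pearson correlation of endpoint strengths, both edge orientations."""
    s = brute_strength(w)
    xs, ys = [], []
    n = len(w)
    for i in range(n):
        for j in range(i + 1, n):
            if w[i][j] > 0:
                xs += [s[i], s[j]]
                ys += [s[j], s[i]]
    xs, ys = np.array(xs), np.array(ys)
    if xs.std() == 0 or ys.std() == 0:
        return 0.0
    return float(np.corrcoef(xs, ys)[0, 1])


def brute_modularity(w: np.ndarray, aff: np.ndarray,
                     gamma: float = 1.0) -> float:
    """Newman weighted Q directly from the double sum."""
    two_w = w.sum()
    k = w.sum(axis=1)
    q = 0.0
    n = len(w)
    for i in range(n):
        for j in range(n):
            if aff[i] == aff[j]:
                q += w[i][j] / two_w - gamma * k[i] * k[j] / (two_w * two_w)
    return q


def brute_trapezoid(x: np.ndarray, y: np.ndarray) -> float:
    total = 0.0
    for a, b, fa, fb in zip(x[:-1], x[1:], y[:-1], y[1:]):
        total += 0.5 * (fa + fb) * (b - a)
    return total


def random_graph(rng: np.random.Generator, n: int, p: float = 0.4,
                 connected: bool = False) -> np.ndarray:
    """Random symmetric nonnegative weighted adjacency, zero diagonal."""
    while True:
        a = (rng.random((n, n)) < p) * rng.uniform(0.1, 2.0, size=(n, n))
        a = np.triu(a, 1)
        a = a + a.T
        if a.sum() == 0:
            continue
        if not connected:
            return a
        if np.isfinite(floyd_warshall(a)).all():
            return a
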