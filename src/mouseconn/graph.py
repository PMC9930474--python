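"""Weighted graph metrics, degree-preserving null models, small-worldness.

Global metrics: node strength, weighted clustering coefficient and
transitivity (geometric-mean / Onnela normalization by default), the
characteristic path length and global efficiency on 1/weight edge lengths,
and strength assortativity. Null models are degree- and weight-preserving
double edge swaps; the small-world index follows the ratio-of-ratios
definition (clustering ratio over path-length ratio against the rewired
ensemble), which exceeds 1 for efficient small-world networks.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import shortest_path

from .types import InsufficientDataError, ValidationError, WeightedGraph

__all__ = [
    "node_strength",
    "degree",
    "clustering_coefficient",
    "transitivity",
    "char_path_length",
    "global_efficiency",
    "assortativity",
    "betweenness_centrality",
    "eigenvector_centrality",
    "distance_matrix",
    "rewire_null",
    "small_world_index",
    "to_networkx",
]


def node_strength(g: WeightedGraph) -> np.ndarray:
    """Sum of edge weights per node."""
    return g.weights.sum(axis=1)


def degree(g: WeightedGraph) -> np.ndarray:
    """Number of nonzero edges per node."""
    return (g.weights > 0).sum(axis=1)


def _normalized_cube_root(g: WeightedGraph) -> np.ndarray:
    wmax = g.weights.max()
    if wmax == 0:
        return np.zeros_like(g.weights)
    return np.cbrt(g.weights / wmax)


def clustering_coefficient(g: WeightedGraph,
                           variant: str = "geometric") -> np.ndarray:
    """Weighted clustering coefficient per node, in [0, 1].

    ``geometric`` (default) uses the geometric mean of triangle weights on
    max-normalized weights; ``arithmetic`` averages the two adjacent edge
    weights of each closed triplet (Barrat-style numerator on normalized
    weights). Nodes with degree < 2 have clustering 0.
    """
    k = degree(g)
    denom = k * (k - 1)
    out = np.zeros(g.n_nodes)
    if variant == "geometric":
        w13 = _normalized_cube_root(g)
        tri = np.diag(w13 @ w13 @ w13)  # 2 x sum of triangle geometric means
        np.divide(tri, denom, out=out, where=denom > 0)
    elif variant == "arithmetic":
        wmax = g.weights.max()
        if wmax > 0:
            wn = g.weights / wmax
            a = (g.weights > 0).astype(float)
            s = wn.sum(axis=1)
            # Barrat: (1/(s_i (k_i - 1))) sum_{jh} (w_ij + w_ih)/2 a_ij a_ih a_jh
            tri = np.einsum("ij,ih,jh->i", wn, a, a)  # sum w_ij over triangles x2
            denom_b = s * (k - 1)
            np.divide(tri, denom_b, out=out, where=denom_b > 0)
    else:
        raise ValidationError("variant must be 'geometric' or 'arithmetic'")
    return np.clip(out, 0.0, 1.0)


def transitivity(g: WeightedGraph) -> float:
    """Global triangle-to-triplet ratio on max-normalized weights."""
    w13 = _normalized_cube_root(g)
    tri = np.trace(w13 @ w13 @ w13)
    k = degree(g)
    triplets = float((k * (k - 1)).sum())
    return float(tri / triplets) if triplets > 0 else 0.0


def distance_matrix(g: WeightedGraph) -> np.ndarray:
    """All-pairs shortest-path lengths on edge lengths 1/weight (Dijkstra)."""
    with np.errstate(divide="ignore"):
        lengths = np.where(g.weights > 0, 1.0 / g.weights, 0.0)
    sp = shortest_path(csr_array(lengths), method="D", directed=False)
    return sp


def char_path_length(g: WeightedGraph) -> float:
    """Mean shortest-path length over connected ordered pairs."""
    d = distance_matrix(g)
    off = ~np.eye(g.n_nodes, dtype=bool)
    finite = np.isfinite(d) & off
    if not finite.any():
        raise InsufficientDataError("fully disconnected graph: CPL undefined")
    return float(d[finite].mean())


def global_efficiency(g: WeightedGraph) -> float:
    """Mean inverse shortest-path length over all ordered pairs (1/inf = 0)."""
    d = distance_matrix(g)
    off = ~np.eye(g.n_nodes, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(d > 0, 1.0 / d, 0.0)
    inv[~np.isfinite(d)] = 0.0
    n = g.n_nodes
    return float(inv[off].sum() / (n * (n - 1))) if n > 1 else 0.0


def assortativity(g: WeightedGraph) -> float:
    """Pearson correlation of node strengths at edge endpoints.

    Both orientations of each undirected edge enter the endpoint list. When
    endpoint strengths are uniform the correlation is undefined; 0 is
    returned with a warning.
    """
    edges = g.edge_list()
    if len(edges) < 2:
        raise InsufficientDataError("need at least 2 edges for assortativity")
    s = node_strength(g)
    a = np.array([s[i] for i, j, _ in edges] + [s[j] for i, j, _ in edges])
    b = np.array([s[j] for i, j, _ in edges] + [s[i] for i, j, _ in edges])
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("uniform endpoint strengths: assortativity undefined, "
                      "returning 0", stacklevel=2)
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def to_networkx(g: WeightedGraph, lengths: bool = False) -> nx.Graph:
    """networkx view of the graph; with ``lengths`` each edge also carries
    ``length`` = 1/weight for shortest-path routines."""
    gx = nx.Graph()
    gx.add_nodes_from(range(g.n_nodes))
    for i, j, w in g.edge_list():
        attrs = {"weight": w}
        if lengths:
            attrs["length"] = 1.0 / w
        gx.add_edge(i, j, **attrs)
    return gx


def betweenness_centrality(g: WeightedGraph,
                           normalized: bool = False) -> np.ndarray:
    """Shortest-path betweenness on 1/weight edge lengths.

    Disconnected graphs are handled per component by the path counting
    itself (pairs in different components contribute nothing).
    """
    gx = to_networkx(g, lengths=True)
    bc = nx.betweenness_centrality(gx, weight="length", normalized=normalized)
    return np.array([bc[i] for i in range(g.n_nodes)])


def eigenvector_centrality(g: WeightedGraph, tol: float = 1e-10,
                           max_iter: int = 10000) -> np.ndarray:
    """Leading eigenvector of the weight matrix by power iteration.

    Computed on the largest connected component (weights elsewhere zeroed
    with a warning), normalized to unit Euclidean norm.
    """
    n = g.n_nodes
    d = distance_matrix(g)
    # connected components from finite distances
    comp = -np.ones(n, dtype=int)
    c = 0
    for i in range(n):
        if comp[i] < 0:
            members = np.isfinite(d[i])
            comp[members] = c
            c += 1
    sizes = np.bincount(comp)
    main = int(np.argmax(sizes))
    keep = comp == main
    if not keep.all():
        warnings.warn("graph disconnected: eigenvector centrality computed "
                      "on the largest component", stacklevel=2)
    w = g.weights[np.ix_(keep, keep)]
    m = keep.sum()
    v = np.full(m, 1.0 / np.sqrt(m))
    if w.max() == 0:
        out = np.zeros(n)
        out[keep] = v
        return out
    for _ in range(max_iter):
        nv = w @ v
        norm = np.linalg.norm(nv)
        if norm == 0:
            break
        nv /= norm
        if np.max(np.abs(nv - v)) < tol:
            v = nv
            break
        v = nv
    out = np.zeros(n)
    out[keep] = np.abs(v)
    return out


def rewire_null(g: WeightedGraph, swaps_per_edge: int = 10,
                seed: int = 0, max_attempt_factor: int = 10) -> WeightedGraph:
    """Degree-preserving randomization by weighted double edge swaps.

    Performs ``swaps_per_edge * |E|`` swaps: two edges (a, b) and (c, d)
    become (a, d) and (c, b), each keeping its weight, so the binary degree
    sequence and the weight multiset are preserved exactly. A swap is only
    applied when it creates no self-loop or duplicate edge. If the attempt
    budget runs out before the target count, the current graph is returned
    with a warning.
    """
    edges = g.edge_list()
    if len(edges) < 2:
        raise InsufficientDataError("need at least 2 edges to rewire")
    rng = np.random.default_rng(seed)
    w = g.weights.copy()
    edge_arr = [(i, j) for i, j, _ in edges]
    target = swaps_per_edge * len(edges)
    budget = max_attempt_factor * target
    done = attempts = 0
    m = len(edge_arr)
    while done < target and attempts < budget:
        attempts += 1
        e1, e2 = rng.integers(0, m, size=2)
        if e1 == e2:
            continue
        a, b = edge_arr[e1]
        c, d = edge_arr[e2]
        if rng.integers(0, 2):
            c, d = d, c
        if len({a, b, c, d}) < 4:
            continue
        if w[a, d] != 0 or w[c, b] != 0:
            continue
        w1, w2 = w[a, b], w[c, d]
        w[a, b] = w[b, a] = 0.0
        w[c, d] = w[d, c] = 0.0
        w[a, d] = w[d, a] = w1
        w[c, b] = w[b, c] = w2
        edge_arr[e1] = (min(a, d), max(a, d))
        edge_arr[e2] = (min(c, b), max(c, b))
        done += 1
    if done < target:
        warnings.warn(f"rewiring stopped after {done}/{target} swaps "
                      "(attempt budget exhausted)", stacklevel=2)
    return WeightedGraph(node_names=list(g.node_names), weights=w)


def small_world_index(g: WeightedGraph, n_null: int = 10,
                      seed: int = 0, swaps_per_edge: int = 10) -> float:
    """Small-world index against a degree-preserving rewired ensemble.

    SWI = (CC_real / CC_null) / (CPL_real / CPL_null) with the null values
    averaged over ``n_null`` rewired graphs; > 1 indicates small-world
    organization (high clustering at near-random path length).
    """
    cc_real = float(clustering_coefficient(g).mean())
    cpl_real = char_path_length(g)
    rng = np.random.default_rng(seed)
    cc_null, cpl_null = [], []
    for _ in range(n_null):
        null = rewire_null(g, swaps_per_edge=swaps_per_edge,
                           seed=int(rng.integers(2**31)))
        cc_null.append(float(clustering_coefficient(null).mean()))
        cpl_null.append(char_path_length(null))
    cc_n = float(np.mean(cc_null))
    cpl_n = float(np.mean(cpl_null))
    if cc_n == 0 or cpl_n == 0:
        raise ValidationError("degenerate null ensemble (zero CC or CPL)")
    return (cc_real / cc_n) / (cpl_real / cpl_n)
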