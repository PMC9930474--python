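"""Community detection: seeded Louvain maximization of weighted modularity
and a consensus partition over many randomized restarts.

Modularity is the Newman weighted statistic

    Q = sum_c [ e_c / W - (s_c / 2W)^2 ]

where W is the total edge weight (each undirected edge counted once), e_c
the weight inside community c, and s_c the summed strength of its nodes.
The maximization starts from singleton communities, sweeps nodes in a
seeded random order moving each to the neighboring community with the
largest Q gain, then aggregates communities into super-nodes and repeats.
The final affiliation for a graph is taken as the median over many
restarts: the number of modules is the median module count, and the
reported affiliation is the run closest to (median count, median Q).
"""

from __future__ import annotations

import numpy as np

from .types import CommunityPartition, InsufficientDataError, WeightedGraph

__all__ = [
    "modularity_q",
    "modularity_louvain",
    "consensus_partition",
    "association_consensus",
]


def _relabel(aff: np.ndarray) -> np.ndarray:
    """Map arbitrary labels to contiguous ids from 1, by first appearance."""
    out = np.empty(len(aff), dtype=int)
    mapping: dict[int, int] = {}
    for k, a in enumerate(aff):
        out[k] = mapping.setdefault(int(a), len(mapping) + 1)
    return out


def modularity_q(g: WeightedGraph, affiliation: np.ndarray,
                 gamma: float = 1.0) -> float:
    """Evaluate weighted Newman modularity of a given affiliation."""
    w = g.weights
    two_w = w.sum()  # = 2W for a symmetric matrix with zero diagonal
    if two_w == 0:
        raise InsufficientDataError("graph has no edges")
    aff = np.asarray(affiliation, dtype=int)
    q = 0.0
    strength = w.sum(axis=1)
    for c in np.unique(aff):
        members = aff == c
        e_c = w[np.ix_(members, members)].sum()  # 2 x within weight
        s_c = strength[members].sum()
        q += e_c / two_w - gamma * (s_c / two_w) ** 2
    return float(q)


def _louvain_pass(w: np.ndarray, rng: np.random.Generator,
                  gamma: float) -> np.ndarray:
    """One level of local node moves; returns community labels (0-based).

    ``w`` may carry diagonal self-loop weight from aggregation; it counts
    toward node strength and total weight but not toward the link weights
    between a node and candidate communities (a self-loop travels with the
    node, so it cancels in the gain comparison).
    """
    n = w.shape[0]
    two_w = w.sum()  # includes diagonal, matching k_i = row sums
    strength = w.sum(axis=1)
    comm = np.arange(n)
    comm_strength = strength.copy()
    neighbors = [np.nonzero(w[i])[0] for i in range(n)]
    neighbors = [nb[nb != i] for i, nb in enumerate(neighbors)]
    nbr_w = [w[i, nb] for i, nb in enumerate(neighbors)]
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            nb = neighbors[i]
            if len(nb) == 0:
                continue
            ci = comm[i]
            cand = comm[nb]
            links = np.bincount(cand, weights=nbr_w[i], minlength=n)
            comm_strength[ci] -= strength[i]
            # relative gain of joining community c (terms constant in c dropped):
            #   k_{i,c}/(2W) - gamma * k_i * S_c / (2W)^2
            scale = gamma * strength[i] / (two_w * two_w)
            gains = links[cand] / two_w - scale * comm_strength[cand]
            own_gain = links[ci] / two_w - scale * comm_strength[ci]
            j = int(np.argmax(gains))
            best = int(cand[j]) if gains[j] > own_gain + 1e-14 else ci
            comm_strength[best] += strength[i]
            if best != ci:
                comm[i] = best
                improved = True
    return comm


def modularity_louvain(g: WeightedGraph, gamma: float = 1.0,
                       seed: int = 0) -> CommunityPartition:
    """Greedy modularity maximization (Louvain), deterministic given seed."""
    if g.weights.sum() == 0:
        raise InsufficientDataError("graph has no edges")
    rng = np.random.default_rng(seed)
    w = g.weights.copy()
    n = g.n_nodes
    node_comm = np.arange(n)  # affiliation of original nodes (0-based)
    while True:
        labels = _louvain_pass(w, rng, gamma)
        labels = _relabel(labels) - 1
        n_comm = labels.max() + 1
        if n_comm == w.shape[0]:
            break  # no merge happened at this level
        # aggregate; diagonal keeps within-community weight as self-loops
        m = np.zeros((w.shape[0], n_comm))
        m[np.arange(w.shape[0]), labels] = 1.0
        w = m.T @ w @ m
        node_comm = labels[node_comm]
        if np.sum(w) - np.trace(w) == 0:
            break  # no weight left between super-nodes
    aff = _relabel(node_comm)
    q = modularity_q(g, aff, gamma=gamma)
    return CommunityPartition(affiliation=aff, q=q, n_iterations=1, seed=seed)


def consensus_partition(g: WeightedGraph, n_iter: int = 1000,
                        seed: int = 0,
                        gamma: float = 1.0) -> CommunityPartition:
    """Median-of-restarts consensus community structure.

    Runs the seeded maximization ``n_iter`` times with derived seeds. The
    consensus module count is the median count across runs; the reported
    affiliation is the run whose (module count, Q) is closest to the pair of
    medians (count first, then Q). All runs' Q values are retained on the
    result as ``all_q`` for diagnostics.
    """
    if n_iter < 1:
        raise InsufficientDataError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    seeds = rng.integers(2**31, size=n_iter)
    runs = [modularity_louvain(g, gamma=gamma, seed=int(s)) for s in seeds]
    counts = np.array([r.n_modules for r in runs])
    qs = np.array([r.q for r in runs])
    med_count = np.median(counts)
    med_q = np.median(qs)
    # closest count first, then closest Q, then lowest seed index
    key = np.lexsort((np.arange(n_iter), np.abs(qs - med_q),
                      np.abs(counts - med_count)))
    best = runs[int(key[0])]
    out = CommunityPartition(affiliation=best.affiliation, q=best.q,
                             n_iterations=n_iter, seed=seed)
    out.all_q = qs  # diagnostics: full Q distribution across restarts
    return out


def association_consensus(g: WeightedGraph, n_iter: int = 100,
                          seed: int = 0, gamma: float = 1.0,
                          tau: float = 0.5) -> CommunityPartition:
    """Alternative consensus via the co-assignment (association) matrix.

    Builds the node-by-node co-assignment frequency over restarts,
    thresholds it at ``tau``, and clusters the thresholded association
    matrix with a final maximization run.
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(2**31, size=n_iter)
    n = g.n_nodes
    assoc = np.zeros((n, n))
    for s in seeds:
        aff = modularity_louvain(g, gamma=gamma, seed=int(s)).affiliation
        assoc += (aff[:, None] == aff[None, :]).astype(float)
    assoc /= n_iter
    assoc[assoc < tau] = 0.0
    np.fill_diagonal(assoc, 0.0)
    ag = WeightedGraph(node_names=list(g.node_names), weights=assoc)
    part = modularity_louvain(ag, gamma=gamma, seed=int(seeds[0]))
    q = modularity_q(g, part.affiliation, gamma=gamma)
    return CommunityPartition(affiliation=part.affiliation, q=q,
                              n_iterations=n_iter, seed=seed)
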