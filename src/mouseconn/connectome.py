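"""Functional connectivity matrices and density-thresholded graphs.

Pearson correlations across all node pairs (censored frames dropped), the
Fisher z transform, bootstrap confidence-interval significance, a |z|
threshold mask for removing weak connections, and proportional edge-density
thresholding. Thresholded graphs keep the z values as weights (the analysis
is weighted, not binarized); negative correlations are discarded by default
before graph metrics, with an absolute-value policy available.
"""

from __future__ import annotations

import warnings

import numpy as np

from .types import (
    ConnectivityMatrix,
    DegenerateSignalError,
    InsufficientDataError,
    RoiTimeSeries,
    ValidationError,
    WeightedGraph,
)

__all__ = [
    "correlate",
    "fisher_z",
    "bootstrap_sig",
    "significance_mask",
    "z_mask",
    "density_threshold",
    "graph_from_matrix",
]

_R_CLIP = 1.0 - 1e-12


def fisher_z(r):
    """Fisher z transform atanh(r), with |r| clipped just below 1."""
    r = np.clip(np.asarray(r, dtype=float), -_R_CLIP, _R_CLIP)
    return np.arctanh(r)


def correlate(series: RoiTimeSeries,
              sig_mask: np.ndarray | None = None) -> ConnectivityMatrix:
    """Pearson correlation of every node pair over non-censored frames."""
    good = series.good_frames()
    if len(good) < 3:
        raise InsufficientDataError("need at least 3 non-censored frames")
    x = series.data[:, good]
    sd = x.std(axis=1)
    dead = np.nonzero(sd == 0)[0]
    if len(dead):
        raise DegenerateSignalError(
            f"zero-variance node(s) on non-censored frames: "
            f"{[series.node_names[i] for i in dead]}")
    r = np.corrcoef(x)
    r = np.clip(r, -1.0, 1.0)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    z = fisher_z(r)
    np.fill_diagonal(z, 0.0)  # diagonal excluded from analysis
    return ConnectivityMatrix(
        node_names=list(series.node_names), r=r, z=z, sig_mask=sig_mask)


def _pearson_rows(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of two equally shaped 2-D arrays.

    Rows with zero variance on either side get r = 0 (degenerate resample).
    """
    xc = xs - xs.mean(axis=1, keepdims=True)
    yc = ys - ys.mean(axis=1, keepdims=True)
    num = np.einsum("ij,ij->i", xc, yc)
    den = np.sqrt(np.einsum("ij,ij->i", xc, xc) * np.einsum("ij,ij->i", yc, yc))
    out = np.zeros(len(num))
    np.divide(num, den, out=out, where=den > 0)
    return out


def bootstrap_sig(x: np.ndarray, y: np.ndarray, b: int = 1000,
                  alpha: float = 0.05,
                  seed: int = 0) -> tuple[bool, tuple[float, float]]:
    """Percentile bootstrap CI for the Pearson correlation of (x, y).

    Pairs are resampled with replacement ``b`` times; the correlation is
    significant when the central 1-alpha interval excludes zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 10:
        raise InsufficientDataError("need at least 10 paired samples")
    if b < 100:
        raise ValidationError("need at least 100 bootstrap resamples")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(b, n))
    rs = _pearson_rows(x[idx], y[idx])
    lo, hi = np.percentile(rs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return bool(lo > 0 or hi < 0), (float(lo), float(hi))


def significance_mask(series: RoiTimeSeries, b: int = 1000,
                      alpha: float = 0.05, seed: int = 0) -> np.ndarray:
    """Bootstrap significance for every node pair of one series.

    Shares one resampling-index matrix across pairs (frames are resampled
    jointly, which preserves the cross-node structure of each resample).
    """
    good = series.good_frames()
    x = series.data[:, good]
    n_nodes, n = x.shape
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(b, n))
    mask = np.zeros((n_nodes, n_nodes), dtype=bool)
    for i in range(n_nodes):
        xi = x[i][idx]
        for j in range(i + 1, n_nodes):
            rs = _pearson_rows(xi, x[j][idx])
            lo, hi = np.percentile(rs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
            mask[i, j] = mask[j, i] = bool(lo > 0 or hi < 0)
    return mask


def z_mask(cm: ConnectivityMatrix, z_cut: float = 2.3,
           negative_edges: str = "discard") -> WeightedGraph:
    """Remove weak connections: keep |z| >= z_cut (and bootstrap-significant
    pairs when a mask is present); weights are the retained z values.

    ``negative_edges``: "discard" zeroes negative weights, "absolute" keeps
    their magnitude.
    """
    if z_cut < 0:
        raise ValidationError("z_cut must be nonnegative")
    if negative_edges not in ("discard", "absolute"):
        raise ValidationError("negative_edges must be 'discard' or 'absolute'")
    w = cm.z.copy()
    np.fill_diagonal(w, 0.0)
    w[np.abs(w) < z_cut] = 0.0
    if cm.sig_mask is not None:
        w[~cm.sig_mask] = 0.0
    if negative_edges == "discard":
        w[w < 0] = 0.0
    else:
        w = np.abs(w)
    return WeightedGraph(node_names=list(cm.node_names), weights=w)


def graph_from_matrix(cm: ConnectivityMatrix,
                      z_cut: float = 0.0,
                      negative_edges: str = "discard") -> WeightedGraph:
    """Base weighted graph for the density sweep (no |z| mask by default)."""
    return z_mask(cm, z_cut=z_cut, negative_edges=negative_edges)


def density_threshold(g: WeightedGraph, density: float) -> WeightedGraph:
    """Keep the k = floor(density * N(N-1)/2) strongest edges.

    Ties are broken by (i, j) lexicographic node order so that repeated runs
    and nested densities are reproducible; the result's density is at most
    the requested one (fewer edges may exist).
    """
    if not 0 < density <= 1:
        raise ValidationError("density must lie in (0, 1]")
    n = g.n_nodes
    pairs = n * (n - 1) // 2
    k = int(np.floor(density * pairs))
    if k == 0:
        warnings.warn("requested density keeps zero edges", stacklevel=2)
        return WeightedGraph(node_names=list(g.node_names),
                             weights=np.zeros_like(g.weights))
    ii, jj = np.nonzero(np.triu(g.weights, 1))
    w = g.weights[ii, jj]
    # sort by descending weight, then ascending (i, j)
    order = np.lexsort((jj, ii, -w))
    keep = order[:k]
    out = np.zeros_like(g.weights)
    out[ii[keep], jj[keep]] = w[keep]
    out += out.T
    return WeightedGraph(node_names=list(g.node_names), weights=out)
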