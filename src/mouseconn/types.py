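"""Core in-memory containers shared across the pipeline.

The analysis operates on four kinds of objects: per-subject ROI time-series
blocks, symmetric connectivity matrices (Pearson r and Fisher z), weighted
graphs obtained by thresholding those matrices, and long-form tables of
per-ROI scalar measures (volume, FA, ADC). Each container validates its own
invariants on construction so downstream stages can assume well-formed input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

GROUPS = ("placebo", "CBD", "THC")
SESSIONS = ("chronic", "washout")

#: columns required of a long-form ROI measure table
MEASURE_COLUMNS = ("subject_id", "group", "session", "roi_name", "measure", "value")
KNOWN_MEASURES = ("volume_mm3", "volume_fraction", "FA", "ADC")


class ValidationError(ValueError):
    """A container or configuration violates one of its invariants."""


class DegenerateSignalError(ValueError):
    """A node's signal carries no usable information (zero norm / variance)."""


class InsufficientDataError(ValueError):
    """Too few usable frames or observations for the requested operation."""


class CollinearityError(ValueError):
    """A regression design matrix is rank deficient."""

    def __init__(self, columns: Sequence[str]):
        self.columns = list(columns)
        super().__init__(f"rank-deficient design; offending columns: {self.columns}")


@dataclass
class RoiTimeSeries:
    """One subject-session block of node-by-time BOLD signals.

    ``data`` is an ``N x T`` array in arbitrary signal units;
    ``censored_frames`` lists time indices flagged as motion spikes, which
    are excluded from every fitted coefficient and from correlations.
    """

    subject_id: str
    group: str
    session: str
    node_names: list[str]
    data: np.ndarray
    sample_interval: float = 1.0
    censored_frames: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.node_names = list(self.node_names)
        self.censored_frames = set(int(f) for f in self.censored_frames)
        self.validate()

    def validate(self) -> None:
        n, t = self.n_nodes, self.n_timepoints
        if self.data.ndim != 2:
            raise ValidationError("data must be a 2-D node x time array")
        if n < 2:
            raise ValidationError("need at least 2 nodes")
        if t < 3:
            raise ValidationError("need at least 3 timepoints")
        if len(set(self.node_names)) != n:
            raise ValidationError("node_names must be unique and match data rows")
        if self.sample_interval <= 0:
            raise ValidationError("sample_interval must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("data contains non-finite values")
        if self.censored_frames and not all(
            0 <= f < t for f in self.censored_frames
        ):
            raise ValidationError("censored_frames outside [0, T)")

    @property
    def n_nodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def good_frames(self) -> np.ndarray:
        """Indices of frames that survive censoring, in time order."""
        mask = np.ones(self.n_timepoints, dtype=bool)
        if self.censored_frames:
            mask[sorted(self.censored_frames)] = False
        return np.nonzero(mask)[0]

    def replace(self, data: np.ndarray | None = None,
                censored_frames: set[int] | None = None) -> "RoiTimeSeries":
        return RoiTimeSeries(
            subject_id=self.subject_id,
            group=self.group,
            session=self.session,
            node_names=list(self.node_names),
            data=self.data.copy() if data is None else data,
            sample_interval=self.sample_interval,
            censored_frames=set(self.censored_frames)
            if censored_frames is None else set(censored_frames),
        )


def _check_symmetric(a: np.ndarray, name: str, tol: float = 1e-12) -> None:
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=tol, rtol=0):
        raise ValidationError(f"{name} must be symmetric within {tol}")


@dataclass
class ConnectivityMatrix:
    """Pearson / Fisher-z connectivity with an optional significance mask.

    ``r`` is symmetric with unit diagonal; ``z = atanh(r)`` off-diagonal
    (the diagonal is excluded from analysis and stored as 0). ``sig_mask``
    marks pairs whose bootstrap confidence interval excludes zero.
    """

    node_names: list[str]
    r: np.ndarray
    z: np.ndarray
    sig_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.node_names = list(self.node_names)
        self.validate()

    def validate(self) -> None:
        n = len(self.node_names)
        if self.r.shape != (n, n) or self.z.shape != (n, n):
            raise ValidationError("r and z must be N x N")
        _check_symmetric(self.r, "r")
        _check_symmetric(self.z, "z")
        if np.any(np.abs(self.r) > 1 + 1e-12):
            raise ValidationError("|r| must not exceed 1")
        if self.sig_mask is not None:
            self.sig_mask = np.asarray(self.sig_mask, dtype=bool)
            if self.sig_mask.shape != (n, n):
                raise ValidationError("sig_mask must be N x N")
            if not np.array_equal(self.sig_mask, self.sig_mask.T):
                raise ValidationError("sig_mask must be symmetric")
            if np.any(np.diag(self.sig_mask)):
                raise ValidationError("sig_mask diagonal must be False")

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)


@dataclass
class WeightedGraph:
    """Symmetric nonnegative weighted adjacency with zero diagonal."""

    node_names: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.node_names = list(self.node_names)
        self.validate()

    def validate(self) -> None:
        n = len(self.node_names)
        if self.weights.shape != (n, n):
            raise ValidationError("weights must be N x N")
        _check_symmetric(self.weights, "weights")
        if np.any(np.diag(self.weights) != 0):
            raise ValidationError("diagonal must be zero")
        if np.any(self.weights < 0):
            raise ValidationError("weights must be nonnegative")

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    @property
    def density(self) -> float:
        n = self.n_nodes
        pairs = n * (n - 1) // 2
        return self.n_edges / pairs if pairs else 0.0

    def edge_list(self) -> list[tuple[int, int, float]]:
        """Upper-triangle edges as (i, j, weight), i < j, lexicographic."""
        ii, jj = np.nonzero(np.triu(self.weights, 1))
        return [(int(i), int(j), float(self.weights[i, j])) for i, j in zip(ii, jj)]


@dataclass
class CommunityPartition:
    """A community assignment with its modularity statistic Q."""

    affiliation: np.ndarray  # length N, module ids contiguous from 1
    q: float
    n_iterations: int
    seed: int

    def __post_init__(self) -> None:
        self.affiliation = np.asarray(self.affiliation, dtype=int)
        ids = np.unique(self.affiliation)
        if not np.array_equal(ids, np.arange(1, len(ids) + 1)):
            raise ValidationError("module ids must be contiguous from 1")
        if not -1.0 - 1e-12 <= self.q <= 1.0 + 1e-12:
            raise ValidationError("Q must lie in [-1, 1]")

    @property
    def n_modules(self) -> int:
        return int(self.affiliation.max())


@dataclass
class ThresholdSweep:
    """Global metrics across an edge-density ladder plus AUC summaries.

    ``records`` is a tidy DataFrame with one row per (density, metric);
    ``auc`` maps metric name to its trapezoidal integral over density.
    """

    densities: np.ndarray
    records: pd.DataFrame  # columns: density, metric, value
    auc: Mapping[str, float]

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        if np.any(self.densities <= 0) or np.any(self.densities > 1):
            raise ValidationError("densities must lie in (0, 1]")
        if np.any(np.diff(self.densities) <= 0):
            raise ValidationError("densities must be strictly increasing")

    def curve(self, metric: str) -> np.ndarray:
        sub = self.records[self.records["metric"] == metric]
        return sub.sort_values("density")["value"].to_numpy()


@dataclass
class NodeMetricsRecord:
    """Per-node metrics evaluated at a single edge density (default 16%)."""

    table: pd.DataFrame  # indexed by node name
    evaluated_at_density: float

    def __post_init__(self) -> None:
        if not 0 < self.evaluated_at_density <= 1:
            raise ValidationError("evaluated_at_density must be in (0, 1]")
        if np.any(self.table["strength"] < 0):
            raise ValidationError("strength must be nonnegative")


def validate_measure_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a long-form measure table's schema and invariants."""
    missing = [c for c in MEASURE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"measure table missing columns: {missing}")
    keys = ["subject_id", "session", "roi_name", "measure"]
    if table.duplicated(subset=keys).any():
        raise ValidationError("duplicate (subject, session, roi, measure) keys")
    frac = table.loc[table["measure"] == "volume_fraction", "value"]
    if len(frac) and (frac.min() < -1e-12 or frac.max() > 1 + 1e-12):
        raise ValidationError("volume_fraction outside [0, 1]")
    fa = table.loc[table["measure"] == "FA", "value"]
    if len(fa) and (fa.min() < -1e-12 or fa.max() > 1 + 1e-12):
        raise ValidationError("FA outside [0, 1]")
    return table
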