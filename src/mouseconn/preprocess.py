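"""ROI-level BOLD time-series cleaning.

Stages, in default order: motion-spike detection/censoring, per-node linear
detrending, zero-phase band-pass filtering (0.01-0.1 Hz), nuisance
regression against motion/tissue regressors, and L2 normalization of each
node's signal vector. Censored frames never contribute to any fitted
coefficient: detrending and nuisance fits use only surviving frames (the
fitted model is then evaluated and subtracted at every frame), and the
correlation stage downstream drops them entirely. The band-pass filter is a
hard frequency-domain mask applied to the full grid, which keeps it
zero-phase and exactly idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import (
    CollinearityError,
    DegenerateSignalError,
    InsufficientDataError,
    RoiTimeSeries,
    ValidationError,
)

__all__ = [
    "NuisanceDesign",
    "detect_spikes",
    "censor",
    "detrend",
    "bandpass",
    "nuisance_regress",
    "l2_normalize",
    "run_chain",
    "DEFAULT_CHAIN",
]

DEFAULT_CHAIN = ("spikes", "detrend", "bandpass", "nuisance", "normalize")


@dataclass
class NuisanceDesign:
    """T x K regressor matrix (motion parameters, mean white-matter and CSF
    signals, spike indicator columns) with column labels."""

    matrix: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.shape[1] != len(self.labels):
            raise ValidationError("labels must match design columns")
        if self.matrix.shape[1] < 1:
            raise ValidationError("need at least one regressor")

    @classmethod
    def from_series(cls, series: RoiTimeSeries,
                    motion: np.ndarray | None = None,
                    wm: np.ndarray | None = None,
                    csf: np.ndarray | None = None,
                    spike_indicators: bool = True) -> "NuisanceDesign":
        """Assemble a design from whatever nuisance sources are available."""
        t = series.n_timepoints
        cols, labels = [], []
        if motion is not None:
            motion = np.atleast_2d(np.asarray(motion, dtype=float))
            if motion.shape[0] != t:
                motion = motion.T
            for k in range(motion.shape[1]):
                cols.append(motion[:, k])
                labels.append(f"motion_{k + 1}")
        for name, sig in (("wm_mean", wm), ("csf_mean", csf)):
            if sig is not None:
                cols.append(np.asarray(sig, dtype=float))
                labels.append(name)
        if spike_indicators:
            for f in sorted(series.censored_frames):
                ind = np.zeros(t)
                ind[f] = 1.0
                cols.append(ind)
                labels.append(f"spike_{f}")
        if not cols:
            raise ValidationError("no nuisance regressors supplied")
        return cls(np.column_stack(cols), labels)


def _frame_diff_stat(data: np.ndarray) -> np.ndarray:
    """Cross-node mean absolute successive difference, one value per frame.

    Frame 0 has no predecessor; its statistic is 0 so it is never flagged.
    """
    d = np.zeros(data.shape[1])
    d[1:] = np.mean(np.abs(np.diff(data, axis=1)), axis=0)
    return d


def detect_spikes(series: RoiTimeSeries, z_cut: float = 4.0) -> set[int]:
    """Flag frames whose frame-to-frame displacement is an outlier.

    The statistic is the cross-node mean absolute successive difference,
    robust-z-scored against its own median/MAD. A transient spike produces
    two large successive differences (into and out of the spike frame); the
    trailing recovery edge is attributed back to the spike frame rather than
    flagged separately, by checking whether the signal returns to its
    pre-spike level.
    """
    if z_cut <= 0:
        raise ValidationError("z_cut must be positive")
    if series.n_timepoints < 3:
        raise InsufficientDataError("need at least 3 frames")
    d = _frame_diff_stat(series.data)
    med = np.median(d[1:])
    mad = np.median(np.abs(d[1:] - med))
    scale = 1.4826 * mad
    if scale == 0:
        scale = np.std(d[1:]) or np.inf
    z = (d - med) / scale
    candidates = sorted(np.nonzero(z > z_cut)[0])

    flagged: set[int] = set()
    for t in candidates:
        if (t - 1) in flagged and t >= 2:
            # large diff may be recovery from the spike at t-1: compare this
            # frame against the last clean frame on the same robust scale
            back = np.mean(np.abs(series.data[:, t] - series.data[:, t - 2]))
            if (back - med) / scale <= z_cut:
                continue
        flagged.add(int(t))
    return flagged


def censor(series: RoiTimeSeries, frames: set[int]) -> RoiTimeSeries:
    """Record additional censored frames in the series metadata."""
    return series.replace(censored_frames=series.censored_frames | set(frames))


def _good_mask(series: RoiTimeSeries) -> np.ndarray:
    mask = np.ones(series.n_timepoints, dtype=bool)
    for f in series.censored_frames:
        mask[f] = False
    return mask


def detrend(series: RoiTimeSeries) -> RoiTimeSeries:
    """Remove each node's least-squares linear trend.

    The intercept and slope are fitted on non-censored frames only and the
    fitted line is subtracted at every frame, so output nodes have zero mean
    and zero best-fit slope over the surviving frames.
    """
    good = _good_mask(series)
    if good.sum() < 3:
        raise InsufficientDataError("fewer than 3 usable frames for detrending")
    t = np.arange(series.n_timepoints, dtype=float)
    design = np.column_stack([np.ones_like(t), t])
    coef, *_ = np.linalg.lstsq(design[good], series.data[:, good].T, rcond=None)
    return series.replace(data=series.data - (design @ coef).T)


def _fill_censored(series: RoiTimeSeries) -> np.ndarray:
    """Data with censored frames linearly interpolated from good neighbours.

    Used only to stabilize the frequency-domain filter: a large spike left
    in place would ring across neighbouring frames. The frames remain
    censored, so the stand-in values never enter a fit or a correlation.
    """
    data = series.data.copy()
    if not series.censored_frames:
        return data
    good = series.good_frames()
    bad = sorted(series.censored_frames)
    for row in data:
        row[bad] = np.interp(bad, good, row[good])
    return data


def bandpass(series: RoiTimeSeries, low_hz: float = 0.01,
             high_hz: float = 0.1,
             consistent_detrend: bool = False) -> RoiTimeSeries:
    """Zero-phase band-pass via a hard mask on the real FFT bins.

    Retains frequency components in [low_hz, high_hz] unchanged and zeroes
    everything else (including DC). Censored frames are interpolated before
    filtering (and stay censored afterwards) so spike energy does not ring
    into their neighbours.

    With ``consistent_detrend`` the component of the linear ramp that leaks
    through the band mask is also projected out, making the
    detrend -> bandpass pair a single orthogonal projection (and hence the
    pair exactly idempotent on uncensored data).
    """
    nyquist = 0.5 / series.sample_interval
    if not 0 <= low_hz < high_hz:
        raise ValidationError("require 0 <= low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValidationError(
            f"high_hz {high_hz} must be below the Nyquist frequency {nyquist}")
    t = series.n_timepoints
    freqs = np.fft.rfftfreq(t, d=series.sample_interval)
    keep = (freqs >= low_hz) & (freqs <= high_hz)

    def mask(block: np.ndarray) -> np.ndarray:
        spec = np.fft.rfft(block, axis=-1)
        spec[..., ~keep] = 0.0
        return np.fft.irfft(spec, n=t, axis=-1)

    data = mask(_fill_censored(series))
    if consistent_detrend:
        ramp = np.arange(t, dtype=float)
        ramp -= ramp.mean()
        m = mask(ramp)
        mm = float(m @ m)
        if mm > 0:
            data -= np.outer(data @ m / mm, m)
    return series.replace(data=data)


def _design_with_intercept(design: NuisanceDesign, good: np.ndarray) -> np.ndarray:
    x = np.column_stack([np.ones(design.matrix.shape[0]), design.matrix])
    rank = np.linalg.matrix_rank(x[good])
    if rank < x.shape[1]:
        # identify offending columns via incremental rank
        bad, cols = [], [np.ones(good.sum())]
        for k, label in enumerate(design.labels):
            trial = np.column_stack(cols + [design.matrix[good, k]])
            if np.linalg.matrix_rank(trial) == trial.shape[1]:
                cols.append(design.matrix[good, k])
            else:
                bad.append(label)
        raise CollinearityError(bad)
    return x


def nuisance_regress(series: RoiTimeSeries,
                     design: NuisanceDesign) -> RoiTimeSeries:
    """OLS residuals of each node against [intercept | design].

    Coefficients are fitted on non-censored frames; the fitted values are
    subtracted everywhere, so residuals at surviving frames are orthogonal
    to every design column.
    """
    if design.matrix.shape[0] != series.n_timepoints:
        raise ValidationError("design rows must equal the number of frames")
    good = _good_mask(series)
    x = _design_with_intercept(design, good)
    coef, *_ = np.linalg.lstsq(x[good], series.data[:, good].T, rcond=None)
    return series.replace(data=series.data - (x @ coef).T)


def l2_normalize(series: RoiTimeSeries) -> RoiTimeSeries:
    """Scale each node's signal vector to unit Euclidean norm."""
    norms = np.linalg.norm(series.data, axis=1)
    zero = np.nonzero(norms == 0)[0]
    if len(zero):
        raise DegenerateSignalError(
            f"zero-norm signal for node(s): "
            f"{[series.node_names[i] for i in zero]}")
    return series.replace(data=series.data / norms[:, None])


def run_chain(series: RoiTimeSeries,
              stages: tuple[str, ...] = DEFAULT_CHAIN,
              z_cut: float = 4.0,
              low_hz: float = 0.01, high_hz: float = 0.1,
              design: NuisanceDesign | None = None) -> RoiTimeSeries:
    """Apply the cleaning stages in the given order.

    The ``nuisance`` stage runs only when a design is supplied: spike frames
    are excluded from every downstream fit by censoring, so indicator
    regressors for them would be redundant (all-zero on surviving frames).
    """
    out = series
    for stage in stages:
        if stage == "spikes":
            out = censor(out, detect_spikes(out, z_cut=z_cut))
        elif stage == "detrend":
            out = detrend(out)
        elif stage == "bandpass":
            out = bandpass(out, low_hz=low_hz, high_hz=high_hz,
                           consistent_detrend="detrend" in stages)
        elif stage == "nuisance":
            # spike frames are already excluded from every fit by censoring,
            # so without an explicit design there is nothing to regress out
            if design is not None:
                out = nuisance_regress(out, design)
        elif stage == "normalize":
            out = l2_normalize(out)
        else:
            raise ValidationError(f"unknown stage: {stage}")
    return out
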