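"""Gap-aware, uniformly sampled time-series container and resampling primitives.

A :class:`SampledSeries` stores one scalar channel on an implicit uniform
grid: sample ``i`` lives at ``start_time + i * dt`` seconds.  Validity is
tracked per sample; the stored value of an invalid sample carries no
information and is never read by any operation in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable

import numpy as np

from .errors import AlignmentError, CadenceError, ConfigurationError

__all__ = ["SampledSeries", "block_average", "moving_filter"]

DEFAULT_START = datetime(2020, 1, 1, 0, 0, 0)


@dataclass
class SampledSeries:
    """Uniformly sampled scalar series with a per-sample validity flag.

    Parameters
    ----------
    values : array-like of float
        Sample values in signal units (mmHg for pressures, dimensionless
        for correlation indices).
    dt : float
        Sampling interval in seconds (must be positive).
    start_time : datetime, optional
        Absolute time of sample 0.
    valid : array-like of bool, optional
        Parallel validity flags; defaults to finite-value detection.
    """

    values: np.ndarray
    dt: float
    start_time: datetime = field(default_factory=lambda: DEFAULT_START)
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if self.valid is None:
            self.valid = np.isfinite(self.values)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.values.shape:
            raise ValueError("values and valid must have identical length")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        self.dt = float(self.dt)

    def __len__(self) -> int:
        return self.values.size

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Recording span in seconds (last sample time + dt)."""
        return self.n * self.dt

    def offsets(self) -> np.ndarray:
        """Sample times in seconds relative to ``start_time``."""
        return np.arange(self.n) * self.dt

    def masked(self) -> np.ndarray:
        """Values with invalid samples replaced by NaN."""
        out = self.values.astype(float).copy()
        out[~self.valid] = np.nan
        return out

    def copy(self) -> "SampledSeries":
        return SampledSeries(
            self.values.copy(), self.dt, self.start_time, self.valid.copy()
        )

    def replace_values(self, values: np.ndarray, valid: np.ndarray) -> "SampledSeries":
        """New series on the same grid with different payload."""
        return SampledSeries(np.asarray(values, float), self.dt, self.start_time,
                             np.asarray(valid, bool))

    def aligned_with(self, other: "SampledSeries") -> bool:
        return self.start_time == other.start_time and self.dt == other.dt

    def require_aligned(self, other: "SampledSeries") -> None:
        if not self.aligned_with(other):
            raise AlignmentError(
                f"series grids differ: start {self.start_time}/{other.start_time}, "
                f"dt {self.dt}/{other.dt}"
            )


def _factor(target_dt: float, dt: float) -> int:
    ratio = target_dt / dt
    factor = int(round(ratio))
    if factor < 1 or abs(ratio - factor) > 1e-9:
        raise CadenceError(
            f"target interval {target_dt} s is not an integer multiple of {dt} s"
        )
    return factor


def block_average(series: SampledSeries, target_dt: float,
                  min_fraction: float = 0.5) -> SampledSeries:
    """Downsample by averaging non-overlapping blocks of samples.

    Each output sample is the mean of the *valid* input samples in its
    block and is flagged invalid when fewer than ``min_fraction`` of the
    block's samples are valid.  A trailing partial block is dropped.
    """
    if not (0 < min_fraction <= 1):
        raise ConfigurationError("min_fraction must be in (0, 1]")
    factor = _factor(target_dt, series.dt)
    n_out = series.n // factor
    if n_out == 0:
        return SampledSeries(np.empty(0), target_dt, series.start_time,
                             np.empty(0, bool))
    vals = np.where(series.valid, series.values, 0.0)[: n_out * factor]
    ok = series.valid[: n_out * factor]
    vals = vals.reshape(n_out, factor)
    ok = ok.reshape(n_out, factor)
    counts = ok.sum(axis=1)
    out_valid = counts >= min_fraction * factor
    with np.errstate(invalid="ignore", divide="ignore"):
        out_vals = np.where(counts > 0, vals.sum(axis=1) / np.maximum(counts, 1), np.nan)
    out_vals = np.where(out_valid, out_vals, np.nan)
    return SampledSeries(out_vals, float(target_dt), series.start_time, out_valid)


def moving_filter(series: SampledSeries, window: float, statistic: str = "mean",
                  alignment: str = "trailing") -> SampledSeries:
    """Trailing (causal) moving mean or median over valid samples.

    The output at ``t_i`` is the statistic over valid samples in the
    half-open interval ``(t_i - window, t_i]``; it is invalid when that
    interval holds no valid sample.  Only trailing alignment is offered:
    the consumer is a prospective bedside algorithm and must not peek
    into the future.
    """
    if alignment != "trailing":
        raise ConfigurationError(f"unsupported alignment {alignment!r}")
    if statistic not in ("mean", "median"):
        raise ConfigurationError(f"unknown statistic {statistic!r}")
    w = _factor(window, series.dt)
    n = series.n
    if n == 0:
        return series.copy()
    # pad the front so every window has w rows, NaN-filled outside the record
    vals = np.concatenate([np.full(w - 1, np.nan), series.masked()])
    windows = np.lib.stride_tricks.sliding_window_view(vals, w)
    counts = np.sum(np.isfinite(windows), axis=1)
    out_valid = counts > 0
    out_vals = _nan_stat(windows, statistic)
    out_vals = np.where(out_valid, out_vals, np.nan)
    return SampledSeries(out_vals, series.dt, series.start_time, out_valid)


def _nan_stat(windows: np.ndarray, statistic: str) -> np.ndarray:
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        if statistic == "mean":
            return np.nanmean(windows, axis=1)
        return np.nanmedian(windows, axis=1)


def downsample_ticks(series: SampledSeries, cadence: float) -> SampledSeries:
    """Pick the samples lying on multiples of ``cadence`` (no averaging)."""
    step = _factor(cadence, series.dt)
    return SampledSeries(series.values[::step].copy(), float(cadence),
                         series.start_time, series.valid[::step].copy())


def regularize(offsets: Iterable[float], values: Iterable[float],
               dt: float, start_offset: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Snap irregular (offset, value) pairs onto a uniform grid.

    Offsets are rounded to the nearest grid point; duplicate hits are
    averaged; grid points never hit are invalid.  Returns (values, valid).
    """
    offs = np.asarray(list(offsets), float)
    vals = np.asarray(list(values), float)
    if offs.size == 0:
        return np.empty(0), np.empty(0, bool)
    idx = np.round((offs - start_offset) / dt).astype(int)
    keep = np.isfinite(vals) & (idx >= 0)
    idx, vals = idx[keep], vals[keep]
    n = int(idx.max()) + 1 if idx.size else 0
    acc = np.zeros(n)
    cnt = np.zeros(n)
    np.add.at(acc, idx, vals)
    np.add.at(cnt, idx, 1.0)
    valid = cnt > 0
    out = np.where(valid, acc / np.maximum(cnt, 1), np.nan)
    return out, valid
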