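"""Delimited-text readers/writers and an optional HDF5 container.

The exchange format is a CSV with a ``datetime`` column (ISO-8601) plus
one column per signal (``abp[mmHg]``, ``icp[mmHg]``); empty cells are
invalid samples.  Irregular timestamps are snapped to the nearest grid
point at read time and duplicate grid hits are averaged.
"""

from __future__ import annotations

from datetime import datetime

import numpy as np
import pandas as pd

from .engine import CppoptTrend
from .timeseries import SampledSeries, regularize

__all__ = ["read_signals", "write_signals", "write_trend", "read_trend",
           "save_hdf5", "load_hdf5"]

ABP_COL = "abp[mmHg]"
ICP_COL = "icp[mmHg]"


def read_signals(path, columns=(ABP_COL, ICP_COL), dt: float | None = None
                 ) -> dict[str, SampledSeries]:
    """Read signal columns from a delimited-text recording.

    Returns a dict keyed by column name.  ``dt`` defaults to the median
    timestamp difference.
    """
    df = pd.read_csv(path)
    if "datetime" not in df.columns:
        raise ValueError(f"{path}: missing 'datetime' column")
    ts = pd.to_datetime(df["datetime"])
    start = ts.iloc[0].to_pydatetime()
    offs = (ts - ts.iloc[0]).dt.total_seconds().to_numpy()
    if dt is None:
        diffs = np.diff(offs)
        diffs = diffs[diffs > 0]
        if diffs.size == 0:
            raise ValueError(f"{path}: cannot infer sampling interval")
        dt = float(np.median(diffs))
    out = {}
    n_grid = int(round(offs[-1] / dt)) + 1
    for col in columns:
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
        vals, valid = regularize(offs, df[col].to_numpy(dtype=float), dt)
        if vals.size < n_grid:  # trailing invalid cells fell off the grid
            pad = n_grid - vals.size
            vals = np.concatenate([vals, np.full(pad, np.nan)])
            valid = np.concatenate([valid, np.zeros(pad, bool)])
        out[col] = SampledSeries(vals, dt, start, valid)
    return out


def _timestamps(series: SampledSeries) -> pd.DatetimeIndex:
    return pd.to_datetime(series.start_time) + pd.to_timedelta(
        series.offsets(), unit="s")


def write_signals(path, series: dict[str, SampledSeries]) -> None:
    """Write named series sharing one grid to a CSV (invalid -> empty cell)."""
    items = list(series.items())
    ref = items[0][1]
    for _, s in items[1:]:
        ref.require_aligned(s)
    data = {"datetime": _timestamps(ref).strftime("%Y-%m-%dT%H:%M:%S")}
    for name, s in items:
        data[name] = s.masked()
    pd.DataFrame(data).to_csv(path, index=False)


def _reason_summary(reasons: dict) -> str:
    return ";".join(f"{k}:{v}" for k, v in sorted(reasons.items()))


def write_trend(path, trend: CppoptTrend) -> None:
    """Write the minute-by-minute engine output to a trend CSV."""
    df = pd.DataFrame({
        "datetime": _timestamps(trend.cpp).strftime("%Y-%m-%dT%H:%M:%S"),
        "cpp": trend.cpp.masked(),
        "prx": trend.prx.masked(),
        "prx_ft": trend.prx_ft.masked(),
        "cppopt_raw": trend.raw.masked(),
        "cppopt": trend.smoothed.masked(),
        "n_windows": trend.contributing_windows,
        "rejection_summary": [_reason_summary(r) for r in trend.rejections],
    })
    df.to_csv(path, index=False)


def read_trend(path) -> dict[str, SampledSeries]:
    """Read a trend CSV back into aligned series (cpp, cppopt, ...)."""
    numeric = ("cpp", "prx", "prx_ft", "cppopt_raw", "cppopt")
    return read_signals(path, columns=tuple(
        c for c in numeric if c in pd.read_csv(path, nrows=0).columns))


def save_hdf5(path, series: dict[str, SampledSeries]) -> None:
    """One dataset per signal plus start_time/dt attributes."""
    import h5py

    with h5py.File(path, "w") as f:
        for name, s in series.items():
            g = f.create_group(name)
            g.create_dataset("values", data=s.values)
            g.create_dataset("valid", data=s.valid)
            g.attrs["dt"] = s.dt
            g.attrs["start_time"] = s.start_time.isoformat()


def load_hdf5(path) -> dict[str, SampledSeries]:
    import h5py

    out = {}
    with h5py.File(path, "r") as f:
        for name in f:
            g = f[name]
            out[name] = SampledSeries(
                g["values"][:], float(g.attrs["dt"]),
                datetime.fromisoformat(g.attrs["start_time"]),
                g["valid"][:].astype(bool))
    return out
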