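"""Trend-quality metrics: stability, yield, optimum deviation, jumps.

These quantify the properties used to judge algorithm variants: a stable
trend (low SD of consecutive differences), high availability (yield),
small signed deviation of CPP from the recommended optimum, few abrupt
jumps, and values inside the plausible clinical range.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .timeseries import SampledSeries

__all__ = ["TrendReport", "stability_index", "yield_pct", "delta_cppopt",
           "count_jumps", "plausible_frac", "trend_report"]

#: consecutive-difference pairs separated by more than this are skipped,
#: so missingness is not conflated with instability
MAX_DIFF_GAP = 600.0


@dataclass
class TrendReport:
    stability_index: float | None
    yield_pct: float | None
    delta_cppopt: float | None
    n_jumps: int
    plausible_frac: float | None
    first_value_time: float | None      # seconds from recording start

    def to_dict(self) -> dict:
        return asdict(self)


def stability_index(trend: SampledSeries) -> float | None:
    """Sample SD of differences between consecutive valid samples (mmHg).

    Lower means more stable.  Pairs straddling a gap longer than 10 min
    are excluded.  Undefined (None) below 3 valid samples / 2 usable
    differences.
    """
    idx = np.nonzero(trend.valid)[0]
    if idx.size < 3:
        return None
    close = (np.diff(idx) * trend.dt) <= MAX_DIFF_GAP
    diffs = np.diff(trend.values[idx])[close]
    if diffs.size < 2:
        return None
    return float(np.std(diffs, ddof=1))


def yield_pct(trend: SampledSeries, cpp: SampledSeries) -> float | None:
    """Percentage of valid-CPP ticks at which the trend is also valid."""
    trend.require_aligned(cpp)
    n = min(trend.n, cpp.n)
    denom = int(cpp.valid[:n].sum())
    if denom == 0:
        return None
    num = int((trend.valid[:n] & cpp.valid[:n]).sum())
    return 100.0 * num / denom


def delta_cppopt(cpp: SampledSeries, trend: SampledSeries) -> float | None:
    """Mean signed deviation CPP - CPPopt over pairwise-valid ticks (mmHg).

    Negative means CPP ran below the recommended optimum.
    """
    cpp.require_aligned(trend)
    n = min(trend.n, cpp.n)
    both = trend.valid[:n] & cpp.valid[:n]
    if not both.any():
        return None
    return float(np.mean(cpp.values[:n][both] - trend.values[:n][both]))


def count_jumps(trend: SampledSeries, threshold: float = 10.0,
                horizon: float = 300.0) -> int:
    """Number of abrupt-change events (> threshold within < horizon).

    A tick is 'jumping' when some valid sample strictly inside the
    preceding horizon differs from it by more than the threshold;
    consecutive jumping ticks collapse into a single event, which ends
    once the difference falls back below the threshold.
    """
    h = max(1, int(np.ceil(horizon / trend.dt)) - 1)  # strictly-within lookback
    flags = np.zeros(trend.n, dtype=bool)
    for i in range(trend.n):
        if not trend.valid[i]:
            continue
        lo = max(0, i - h)
        prev = trend.values[lo:i][trend.valid[lo:i]]
        if prev.size and np.any(np.abs(trend.values[i] - prev) > threshold):
            flags[i] = True
    return int(np.sum(flags[1:] & ~flags[:-1]) + (1 if flags[:1].any() else 0))


def plausible_frac(trend: SampledSeries, lo: float = 50.0,
                   hi: float = 100.0) -> float | None:
    """Fraction of valid samples strictly inside the plausible range."""
    v = trend.values[trend.valid]
    if v.size == 0:
        return None
    return float(np.mean((v > lo) & (v < hi)))


def trend_report(trend: SampledSeries, cpp: SampledSeries) -> TrendReport:
    """Assemble the full report for one CPPopt trend against its CPP."""
    idx = np.nonzero(trend.valid)[0]
    first = float(idx[0] * trend.dt) if idx.size else None
    return TrendReport(
        stability_index=stability_index(trend),
        yield_pct=yield_pct(trend, cpp),
        delta_cppopt=delta_cppopt(cpp, trend),
        n_jumps=count_jumps(trend),
        plausible_frac=plausible_frac(trend),
        first_value_time=first,
    )
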