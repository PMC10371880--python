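"""Multi-window weighted CPPopt engine.

Every minute, PRx-vs-CPP scatter from 36 trailing windows (2 h 10 min to
8 h in 10-min steps at defaults) is binned into 5-mmHg CPP bins, a
quadratic is fitted to the bin means on the Fisher-transformed PRx scale,
each fit is judged against the acceptance-criteria stack, surviving nadirs
are combined by weighted average, and the minute-by-minute result is
smoothed with an exponentially weighted average over a 2-h buffer.

Two weighting schemes are provided through one code path:

* ``"new"`` — weight = R²_full for accepted parabolic fits, else 0;
* ``"previous"`` — weight = exp(-window hours) * exp(-fit RMSE) for
  accepted fits, else 0 (the earlier production variant, which also skips
  the R²_full criterion and uses looser bin-count limits).
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .prx import compute_prx
from .timeseries import SampledSeries, moving_filter

__all__ = [
    "CppoptConfig", "BinnedCurve", "WindowFit", "CppoptTrend",
    "enumerate_windows", "bin_window", "fit_and_judge", "r2_full",
    "window_weight", "combine_windows", "ewa_smooth", "compute_cppopt",
]

# rejection reasons, in pipeline order
REASON_TOO_FEW_BINS = "too_few_bins"
REASON_MISSING_DATA = "missing_data"
REASON_INCLUDED_DATA = "included_data"
REASON_NON_PARABOLIC = "non_parabolic"
REASON_Y_SPAN = "y_span"
REASON_Y_REGION = "y_region"
REASON_R2_FULL = "r2_full"


@dataclass(frozen=True)
class CppoptConfig:
    """Full curve-fitting and weighting parameter set.

    Defaults correspond to the fine-tuned ("new") variant; use
    :meth:`previous` for the earlier moving-average variant.  Thresholds
    on the PRx axis (``min_y_span``, ``y_region_*``) apply on the
    Fisher-transformed scale, which is the scale the curve is fitted on.
    """

    cpp_prefilter: str = "median"          # {mean|median}, previous: mean
    cpp_prefilter_window: float = 300.0    # seconds
    n_bins: int = 16
    bin_min: float = 40.0                  # mmHg
    bin_max: float = 120.0                 # mmHg
    min_bin_count_frac: float = 0.03       # previous: 0.02
    min_included_frac: float = 0.5
    min_y_span: float = 0.2                # Fisher-PRx units
    y_region_min: float = -0.3
    y_region_max: float = 0.6
    r2_full_min: float | None = 0.2        # previous: None (criterion disabled)
    weighting: str = "new"                 # {new|previous}
    window_min: float = 7200.0             # seconds
    window_max: float = 28800.0
    window_step: float = 600.0
    n_windows: int = 36
    ewa_alpha: float = 0.1
    ewa_window: float = 7200.0
    missing_data_limit: float = 0.5
    update_cadence: float = 60.0
    prx_window: float = 300.0
    prx_min_pairs: int = 15

    def __post_init__(self) -> None:
        if self.cpp_prefilter not in ("mean", "median"):
            raise ConfigurationError(f"unknown prefilter {self.cpp_prefilter!r}")
        if self.weighting not in ("new", "previous"):
            raise ConfigurationError(f"unknown weighting {self.weighting!r}")
        if not self.bin_min < self.bin_max:
            raise ConfigurationError("bin_min must be below bin_max")
        if self.n_bins < 1:
            raise ConfigurationError("n_bins must be positive")
        if not 0 < self.ewa_alpha < 1:
            raise ConfigurationError("ewa_alpha must lie in (0, 1)")
        if not 0 < self.missing_data_limit <= 1:
            raise ConfigurationError("missing_data_limit must lie in (0, 1]")
        if self.window_min > self.window_max:
            raise ConfigurationError("window_min must not exceed window_max")
        enumerate_windows(self)  # fail fast on an inconsistent quadruple

    @classmethod
    def previous(cls, **overrides) -> "CppoptConfig":
        """The earlier (moving-average, 'CPPopt_MA') variant."""
        base = dict(cpp_prefilter="mean", min_bin_count_frac=0.02,
                    r2_full_min=None, weighting="previous")
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_dict(cls, data: dict) -> "CppoptConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        variant = data.get("weighting", "new")
        if variant == "previous":
            return cls.previous(**{k: v for k, v in data.items() if k != "weighting"})
        return cls(**data)

    def replace(self, **changes) -> "CppoptConfig":
        return dataclasses.replace(self, **changes)

    @property
    def bin_width(self) -> float:
        return (self.bin_max - self.bin_min) / self.n_bins

    @property
    def bin_edges(self) -> np.ndarray:
        return self.bin_min + self.bin_width * np.arange(self.n_bins + 1)


def enumerate_windows(config: CppoptConfig) -> np.ndarray:
    """Ordered look-back window lengths (seconds), strictly increasing.

    The enumeration runs from ``window_min + window_step`` up to
    ``window_max`` so that exactly ``n_windows`` lengths are produced and
    the longest window (which anchors the warm-up requirement) stays
    exact: 2 h .. 8 h by 10 min nominally spans 37 grid points, but the
    scheme uses 36 windows, so the shortest grid point is dropped.
    """
    n, lo, hi, step = (config.n_windows, config.window_min,
                       config.window_max, config.window_step)
    if n == 1 and lo == hi:
        return np.array([float(hi)])
    if n < 1 or step <= 0:
        raise ConfigurationError("need n_windows >= 1 and window_step > 0")
    if abs(lo + n * step - hi) > 1e-6:
        raise ConfigurationError(
            f"inconsistent window quadruple: window_min + n_windows * window_step "
            f"= {lo} + {n} * {step} = {lo + n * step} != window_max = {hi}"
        )
    return hi - step * np.arange(n - 1, -1, -1.0)


@dataclass
class BinnedCurve:
    """Per-bin summary of one window's PRx_ft-vs-CPP scatter.

    Bins partition ``[bin_min, bin_max)`` into half-open intervals.
    ``included`` marks bins populated enough to enter the curve fit;
    empty bins are never included, but non-empty excluded bins still
    count toward R²_full.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    mean_cpp: np.ndarray      # NaN for empty bins
    mean_y: np.ndarray        # Fisher-PRx; NaN for empty bins
    included: np.ndarray

    @property
    def n_included(self) -> int:
        return int(self.included.sum())


@dataclass
class WindowFit:
    """Outcome of fitting and judging one look-back window."""

    window_length: float
    coefficients: tuple[float, float, float] | None = None  # a, b, c
    r2_full: float = 0.0
    rmse: float = float("nan")          # included-bin residual RMSE
    shape: str = "no-fit"               # {parabolic|non-parabolic|no-fit}
    candidate_opt: float | None = None
    rejection_reason: str | None = None
    weight: float = 0.0


@dataclass
class CppoptTrend:
    """Minute-by-minute engine output with provenance."""

    raw: SampledSeries                   # pre-EWA weighted-average CPPopt
    smoothed: SampledSeries              # post-EWA CPPopt
    contributing_windows: np.ndarray     # accepted fits per tick
    cpp: SampledSeries                   # pre-filtered CPP at update cadence
    prx: SampledSeries
    prx_ft: SampledSeries
    rejections: list[dict] = field(default_factory=list)  # reason -> count per tick
    warmed_up: bool = True


def _build_curve(counts: np.ndarray, sum_cpp: np.ndarray, sum_y: np.ndarray,
                 total_count: float, config: CppoptConfig) -> BinnedCurve:
    nonempty = counts > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_cpp = np.where(nonempty, sum_cpp / np.maximum(counts, 1), np.nan)
        mean_y = np.where(nonempty, sum_y / np.maximum(counts, 1), np.nan)
    threshold = max(config.min_bin_count_frac * total_count, 1.0)
    included = counts >= threshold
    return BinnedCurve(config.bin_edges, counts.astype(float), mean_cpp,
                       mean_y, included)


def bin_window(cpp: SampledSeries, prx_ft: SampledSeries, window_length: float,
               at: float, config: CppoptConfig) -> tuple[BinnedCurve, int]:
    """Bin the pairwise-valid (CPP, PRx_ft) samples of one trailing window.

    ``at`` is the window's right edge in seconds from series start.
    Samples with CPP outside ``[bin_min, bin_max)`` are discarded from the
    bins but still count toward the returned window total (they are data
    the fitted curve fails to cover).  Returns (curve, total_count).
    """
    cpp.require_aligned(prx_ft)
    t = cpp.offsets()
    n = min(cpp.n, prx_ft.n)
    sel = (t[:n] > at - window_length) & (t[:n] <= at)
    ok = sel & cpp.valid[:n] & prx_ft.valid[:n]
    c = cpp.values[:n][ok]
    y = prx_ft.values[:n][ok]
    total = int(ok.sum())
    in_range = (c >= config.bin_min) & (c < config.bin_max)
    idx = ((c[in_range] - config.bin_min) // config.bin_width).astype(int)
    counts = np.bincount(idx, minlength=config.n_bins).astype(float)
    sum_cpp = np.bincount(idx, weights=c[in_range], minlength=config.n_bins)
    sum_y = np.bincount(idx, weights=y[in_range], minlength=config.n_bins)
    return _build_curve(counts, sum_cpp, sum_y, total, config), total


def _quadfit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares quadratic y = a x^2 + b x + c (centered for conditioning).

    Solves the 3x3 normal equations in closed form; falls back to lstsq
    when the moment matrix is (near-)singular, e.g. under 3 distinct
    abscissae, where the minimum-norm solution is taken.
    """
    k = x.size
    m = x.sum() / k
    u = x - m
    u2 = u * u
    s1 = u.sum()
    s2 = u2.sum()
    s3 = (u2 * u).sum()
    s4 = (u2 * u2).sum()
    t0 = y.sum()
    t1 = (y * u).sum()
    t2 = (y * u2).sum()
    det = (s4 * (s2 * k - s1 * s1) - s3 * (s3 * k - s1 * s2)
           + s2 * (s3 * s1 - s2 * s2))
    scale = max(s4 * s2 * k, 1e-30)
    if abs(det) > 1e-10 * scale:
        a = (t2 * (s2 * k - s1 * s1) - s3 * (t1 * k - s1 * t0)
             + s2 * (t1 * s1 - s2 * t0)) / det
        bu = (s4 * (t1 * k - t0 * s1) - t2 * (s3 * k - s1 * s2)
              + s2 * (s3 * t0 - t1 * s2)) / det
        cu = (s4 * (s2 * t0 - t1 * s1) - s3 * (s3 * t0 - t1 * s2)
              + t2 * (s3 * s1 - s2 * s2)) / det
    else:
        design = np.column_stack([u2, u, np.ones_like(u)])
        (a, bu, cu), *_ = np.linalg.lstsq(design, y, rcond=None)
    b = bu - 2.0 * a * m
    c = a * m * m - bu * m + cu
    return float(a), float(b), float(c)


def _poly(coeffs: tuple[float, float, float], x: np.ndarray) -> np.ndarray:
    a, b, c = coeffs
    return (a * x + b) * x + c


def r2_full(curve: BinnedCurve, coefficients: tuple[float, float, float]) -> float:
    """Coefficient of determination over ALL non-empty bins, floored at 0.

    Excluded-but-populated bins count too, so a curve that only explains
    the bins it was fitted on is penalized.  Zero variance across bins is
    degenerate and reported as 0.
    """
    nonempty = curve.counts > 0
    if nonempty.sum() < 2:
        return 0.0
    y = curve.mean_y[nonempty]
    yhat = _poly(coefficients, curve.mean_cpp[nonempty])
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 0.0:
        return 0.0
    ss_res = float(np.sum((y - yhat) ** 2))
    return max(0.0, 1.0 - ss_res / ss_tot)


def fit_and_judge(curve: BinnedCurve, total_count: float, config: CppoptConfig,
                  window_length: float = float("nan")) -> WindowFit:
    """Fit a quadratic to the included bins and run the acceptance stack.

    Criteria are applied in a fixed order — (1) enough included data,
    (2) parabolic shape, (3) minimum Y span, (4) Y region overlap,
    (5) R²_full (skipped when the criterion is disabled) — and the first
    failure is recorded as the rejection reason.  All failures are
    verdicts, never exceptions.
    """
    fit = WindowFit(window_length=window_length)
    inc = curve.included & (curve.counts > 0)
    if inc.sum() < 3:
        fit.rejection_reason = REASON_TOO_FEW_BINS
        return fit

    x = curve.mean_cpp[inc]
    y = curve.mean_y[inc]
    coeffs = _quadfit(x, y)
    fit.coefficients = coeffs
    fit.r2_full = r2_full(curve, coeffs)
    fit.rmse = float(np.sqrt(np.mean((y - _poly(coeffs, x)) ** 2)))

    x_lo, x_hi = float(x.min()), float(x.max())
    a, b, _ = coeffs
    vertex = -b / (2.0 * a) if a != 0.0 else float("nan")
    # a nadir outside the observed CPP range is not an observed optimum
    parabolic = a > 0.0 and x_lo <= vertex <= x_hi
    fit.shape = "parabolic" if parabolic else "non-parabolic"

    y_ends = _poly(coeffs, np.array([x_lo, x_hi]))
    y_candidates = list(y_ends)
    if x_lo <= vertex <= x_hi and np.isfinite(vertex):
        y_candidates.append(float(_poly(coeffs, np.array([vertex]))[0]))
    y_min, y_max = float(min(y_candidates)), float(max(y_candidates))

    if curve.counts[inc].sum() < config.min_included_frac * total_count:
        fit.rejection_reason = REASON_INCLUDED_DATA
    elif not parabolic:
        fit.rejection_reason = REASON_NON_PARABOLIC
    elif y_max - y_min < config.min_y_span:
        fit.rejection_reason = REASON_Y_SPAN
    elif y_min > config.y_region_max or y_max < config.y_region_min:
        fit.rejection_reason = REASON_Y_REGION
    elif config.r2_full_min is not None and fit.r2_full < config.r2_full_min:
        fit.rejection_reason = REASON_R2_FULL
    else:
        fit.candidate_opt = float(vertex)
    return fit


def window_weight(fit: WindowFit, config: CppoptConfig) -> float:
    """Weight of one window's candidate optimum in the combination step.

    New scheme: R²_full for accepted parabolic fits, zero otherwise.
    Previous scheme: exp(-L) * exp(-rmse) with L the window length in
    hours and rmse the included-bin residual RMSE in Fisher-PRx units
    (the non-parabolic factor is 0/1 and folds into acceptance).
    """
    if fit.candidate_opt is None:
        return 0.0
    if config.weighting == "new":
        return fit.r2_full
    hours = fit.window_length / 3600.0
    return float(np.exp(-hours) * np.exp(-fit.rmse))


def combine_windows(fits: list[WindowFit]) -> tuple[float | None, int]:
    """Weighted average of the accepted candidate optima of one tick."""
    num = 0.0
    den = 0.0
    n = 0
    for f in fits:
        if f.weight > 0.0 and f.candidate_opt is not None:
            num += f.weight * f.candidate_opt
            den += f.weight
            n += 1
    if den <= 0.0:
        return None, 0
    return num / den, n


def ewa_smooth(raw: SampledSeries, config: CppoptConfig) -> SampledSeries:
    """Exponentially weighted average with weights (1 - alpha)^k.

    ``k`` counts samples back from the current tick; only samples with
    ``k * cadence < ewa_window`` contribute.  A tick is invalid when no
    valid raw sample falls inside the buffer.
    """
    k_max = int(round(config.ewa_window / config.update_cadence))
    w = (1.0 - config.ewa_alpha) ** np.arange(k_max)
    x0 = np.where(raw.valid, raw.values, 0.0)
    v = raw.valid.astype(float)
    num = np.convolve(x0, w)[: raw.n]
    den = np.convolve(v, w)[: raw.n]
    valid = den > 0.0
    vals = np.where(valid, num / np.maximum(den, 1e-300), np.nan)
    return SampledSeries(vals, raw.dt, raw.start_time, valid)


def compute_cppopt(abp10: SampledSeries, icp10: SampledSeries,
                   config: CppoptConfig | None = None) -> CppoptTrend:
    """Run the full pipeline on aligned 10-s ABP and ICP series.

    CPP = ABP - ICP is pre-filtered (5-min median at new defaults), PRx is
    computed and Fisher transformed, and at every update tick past warm-up
    the multi-window fit/judge/weight/combine stack runs, followed by the
    EWA smoother.  No output is produced until the accumulated valid input
    time inside the maximal look-back buffer reaches
    ``missing_data_limit * window_max`` (4 h at defaults).
    """
    if config is None:
        config = CppoptConfig()
    abp10.require_aligned(icp10)
    dt = abp10.dt
    n10 = min(abp10.n, icp10.n)
    step = int(round(config.update_cadence / dt))

    ok_in = abp10.valid[:n10] & icp10.valid[:n10]
    cpp_vals = np.where(ok_in, abp10.values[:n10] - icp10.values[:n10], np.nan)
    cpp10 = SampledSeries(cpp_vals, dt, abp10.start_time, ok_in)
    cpp10f = moving_filter(cpp10, config.cpp_prefilter_window, config.cpp_prefilter)

    n60 = (n10 - 1) // step + 1 if n10 else 0
    cadence = config.update_cadence
    cpp60 = SampledSeries(cpp10f.values[::step][:n60].copy(), cadence,
                          abp10.start_time, cpp10f.valid[::step][:n60].copy())
    prx_res = compute_prx(abp10, icp10, window=config.prx_window,
                          cadence=cadence, min_pairs=config.prx_min_pairs)
    prx60, prxft60 = prx_res.prx, prx_res.prx_ft

    pair = cpp60.valid & prxft60.valid
    cppv = np.where(pair, cpp60.values, config.bin_min - 1.0)  # sentinel: out of range
    yv = np.where(pair, prxft60.values, 0.0)
    in_range = pair & (cppv >= config.bin_min) & (cppv < config.bin_max)
    width = config.bin_width
    binidx = np.zeros(n60, dtype=int)
    binidx[in_range] = np.minimum(
        ((cppv[in_range] - config.bin_min) // width).astype(int), config.n_bins - 1)

    # prefix sums over ticks: per-bin count / sum(CPP) / sum(PRx_ft), pair total
    onehot = np.zeros((config.n_bins, n60))
    cols = np.nonzero(in_range)[0]
    onehot[binidx[cols], cols] = 1.0
    z = np.zeros((config.n_bins, 1))
    cnt_c = np.hstack([z, np.cumsum(onehot, axis=1)])
    sx_c = np.hstack([z, np.cumsum(onehot * np.where(in_range, cppv, 0.0), axis=1)])
    sy_c = np.hstack([z, np.cumsum(onehot * yv, axis=1)])
    tot_c = np.concatenate([[0.0], np.cumsum(pair.astype(float))])

    # warm-up gate: valid input seconds inside the trailing maximal buffer
    cin = np.concatenate([[0.0], np.cumsum(ok_in.astype(float))])
    wmax10 = int(round(config.window_max / dt))
    ticks10 = np.arange(n60) * step + 1
    gate_lo = np.maximum(0, ticks10 - wmax10)
    gate = (cin[np.minimum(ticks10, n10)] - cin[gate_lo]) * dt \
        >= config.missing_data_limit * config.window_max

    wlens = enumerate_windows(config)
    wsamps = np.round(wlens / cadence).astype(int)

    raw_vals = np.full(n60, np.nan)
    raw_valid = np.zeros(n60, dtype=bool)
    contributing = np.zeros(n60, dtype=int)
    rejections: list[dict] = [{} for _ in range(n60)]

    for i in np.nonzero(gate)[0]:
        hi = i + 1
        los = np.maximum(0, hi - wsamps)
        totcs = tot_c[hi] - tot_c[los]
        cnts = cnt_c[:, hi][:, None] - cnt_c[:, los]
        sxs = sx_c[:, hi][:, None] - sx_c[:, los]
        sys_ = sy_c[:, hi][:, None] - sy_c[:, los]
        fits: list[WindowFit] = []
        reasons: Counter = Counter()
        for j, (L, w) in enumerate(zip(wlens, wsamps)):
            if totcs[j] < config.missing_data_limit * w:
                reasons[REASON_MISSING_DATA] += 1
                continue
            curve = _build_curve(cnts[:, j], sxs[:, j], sys_[:, j], totcs[j], config)
            f = fit_and_judge(curve, totcs[j], config, window_length=float(L))
            f.weight = window_weight(f, config)
            fits.append(f)
            if f.rejection_reason is not None:
                reasons[f.rejection_reason] += 1
        value, n_acc = combine_windows(fits)
        if value is not None:
            raw_vals[i] = value
            raw_valid[i] = True
            contributing[i] = n_acc
        rejections[i] = dict(reasons)

    raw = SampledSeries(raw_vals, cadence, abp10.start_time, raw_valid)
    smoothed = ewa_smooth(raw, config)
    return CppoptTrend(raw=raw, smoothed=smoothed, contributing_windows=contributing,
                       cpp=cpp60, prx=prx60, prx_ft=prxft60, rejections=rejections,
                       warmed_up=bool(gate.any()))
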