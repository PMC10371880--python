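"""Pressure-reactivity index (PRx) and its Fisher transform.

PRx is the moving Pearson correlation between 10-s averaged ABP and ICP
over a trailing 5-min window, emitted once per minute.  The Fisher
transform (arctanh) unbounds the correlation before any averaging or
curve fitting downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .timeseries import SampledSeries
from .errors import CadenceError

__all__ = ["PrxSeries", "compute_prx", "fisher"]

#: clip margin applied before arctanh so that +/-1 stays finite
CLIP_EPS = 1e-6

#: variance below this (in squared signal units) is treated as constant
_VAR_TINY = 1e-12


@dataclass
class PrxSeries:
    """Minute-cadence PRx trend plus its Fisher-transformed twin."""

    prx: SampledSeries
    prx_ft: SampledSeries
    window: float = 300.0
    cadence: float = 60.0


def fisher(prx, clip_eps: float = CLIP_EPS):
    """Fisher transform arctanh(r) with boundary clipping.

    Values are clipped into [-1 + clip_eps, 1 - clip_eps] first, so the
    closed interval [-1, 1] always maps to a finite number.  Odd and
    strictly increasing; exact inverse of tanh away from the clip
    boundary.
    """
    r = np.clip(prx, -1.0 + clip_eps, 1.0 - clip_eps)
    return np.arctanh(r)


def compute_prx(abp10: SampledSeries, icp10: SampledSeries, window: float = 300.0,
                cadence: float = 60.0, min_pairs: int = 15) -> PrxSeries:
    """Moving ABP-ICP Pearson correlation on the 10-s grid.

    At each cadence tick ``t`` the correlation is taken over the
    pairwise-valid samples in ``(t - window, t]``.  The output sample is
    invalid when fewer than ``min_pairs`` valid pairs are present or when
    either signal is (numerically) constant in the window — a correlation
    of a constant is undefined and silently emitting 0 would bias the
    downstream curve fit.
    """
    abp10.require_aligned(icp10)
    dt = abp10.dt
    for name, span in (("window", window), ("cadence", cadence)):
        if abs(span / dt - round(span / dt)) > 1e-9:
            raise CadenceError(f"{name} {span} s is not a multiple of dt {dt} s")
    step = int(round(cadence / dt))
    wlen = int(round(window / dt))

    n10 = min(abp10.n, icp10.n)
    ok = abp10.valid[:n10] & icp10.valid[:n10]
    x = np.where(ok, abp10.values[:n10], 0.0)
    y = np.where(ok, icp10.values[:n10], 0.0)

    # prefix sums (index i holds the sum over samples < i)
    c_n = np.concatenate([[0.0], np.cumsum(ok)])
    c_x = np.concatenate([[0.0], np.cumsum(x)])
    c_y = np.concatenate([[0.0], np.cumsum(y)])
    c_xx = np.concatenate([[0.0], np.cumsum(x * x)])
    c_yy = np.concatenate([[0.0], np.cumsum(y * y)])
    c_xy = np.concatenate([[0.0], np.cumsum(x * y)])

    n_out = (n10 - 1) // step + 1 if n10 else 0
    ticks = np.arange(n_out) * step          # 10-s index of each tick
    hi = ticks + 1
    lo = np.maximum(0, hi - wlen)

    n = c_n[hi] - c_n[lo]
    sx = c_x[hi] - c_x[lo]
    sy = c_y[hi] - c_y[lo]
    sxx = c_xx[hi] - c_xx[lo]
    syy = c_yy[hi] - c_yy[lo]
    sxy = c_xy[hi] - c_xy[lo]

    with np.errstate(invalid="ignore", divide="ignore"):
        vx = n * sxx - sx * sx
        vy = n * syy - sy * sy
        cov = n * sxy - sx * sy
        denom = np.sqrt(np.maximum(vx, 0.0) * np.maximum(vy, 0.0))
        r = np.where(denom > 0, cov / np.maximum(denom, _VAR_TINY), np.nan)
    # scale-aware constancy check: variance per sample below tiny absolute floor
    degenerate = (vx <= _VAR_TINY * np.maximum(n, 1)) | (vy <= _VAR_TINY * np.maximum(n, 1))
    valid = (n >= min_pairs) & ~degenerate
    r = np.clip(np.where(valid, r, np.nan), -1.0, 1.0)

    prx = SampledSeries(r, cadence, abp10.start_time, valid)
    ft = np.where(valid, fisher(np.where(valid, r, 0.0)), np.nan)
    prx_ft = SampledSeries(ft, cadence, abp10.start_time, valid.copy())
    return PrxSeries(prx=prx, prx_ft=prx_ft, window=window, cadence=cadence)
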