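"""Surrogate-noise generation and virtual patients with a known optimum.

Two generators support validation of the CPPopt engine:

* :func:`phase_randomize` builds pure-noise surrogates that keep a
  signal's amplitude spectrum but destroy all cross-signal relationships,
  for false-positive testing;
* :func:`simulate_patient` builds 10-s ABP/ICP pairs whose windowed
  ABP-ICP correlation (the quantity PRx estimates) follows a programmable
  U-shaped function of CPP, so the ground-truth optimum is known exactly.

Both operate at the 10-s (not waveform) level: the algorithm under test
consumes 10-s averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GapError, PatientSpecError
from .timeseries import SampledSeries

__all__ = ["VirtualPatientSpec", "phase_randomize", "simulate_patient"]

#: linkage block length in 10-s samples (5 min, the PRx estimator window)
BLOCK = 30


def phase_randomize(series: SampledSeries, seed: int) -> SampledSeries:
    """Fourier phase-randomized surrogate of a gap-free series.

    The amplitude spectrum (hence mean and variance) is preserved exactly;
    phases of all non-DC, non-Nyquist components are drawn uniformly, and
    conjugate symmetry keeps the output real.
    """
    if not series.valid.all():
        raise GapError("phase randomization requires a gap-free series")
    n = series.n
    if n < 4:
        raise GapError("series too short to randomize (need length >= 4)")
    rng = np.random.default_rng(seed)
    spec = np.fft.rfft(series.values)
    mags = np.abs(spec)
    phases = np.angle(spec)
    # randomize everything except DC; keep Nyquist (real by construction) as is
    hi = spec.size - 1 if n % 2 == 0 else spec.size
    phases[1:hi] = rng.uniform(0.0, 2.0 * np.pi, hi - 1)
    out = np.fft.irfft(mags * np.exp(1j * phases), n)
    return SampledSeries(out, series.dt, series.start_time,
                         np.ones(n, dtype=bool))


@dataclass
class VirtualPatientSpec:
    """Ground-truth description of one simulated recording.

    ``prx_curve`` maps CPP (mmHg) to the target ABP-ICP correlation via
    quadratic coefficients (a, b, c); evaluations are clipped to
    [-0.99, 0.99].  When omitted it is built as
    ``prx_floor + prx_curvature * (CPP - true_opt)^2``, which puts the
    correlation minimum exactly at ``true_opt``.

    The CPP trajectory is a bounded random walk stepped once per 5-min
    block and held constant inside the block, so windowed correlations
    are controlled at the scale PRx measures them.
    """

    duration: float = 36000.0          # seconds
    true_opt: float = 75.0             # mmHg
    prx_curve: tuple[float, float, float] | None = None
    prx_floor: float = -0.3
    prx_curvature: float = 0.005       # correlation units per mmHg^2
    cpp_mean: float | None = None      # walk start; defaults to true_opt
    cpp_drift_sd: float = 4.0          # mmHg per 5-min step
    cpp_min: float | None = None       # walk bounds; default true_opt -/+ 15
    cpp_max: float | None = None
    icp_baseline: float = 12.0         # mmHg
    icp_drift_sd: float = 0.8          # mmHg per 5-min step
    wave_sd: float = 4.0               # ABP slow-wave amplitude, mmHg
    wave_ar1: float = 0.0              # lag-1 autocorrelation of the 10-s waves
    icp_wave_sd: float = 2.0           # correlated ICP fluctuation, mmHg
    noise_sd: float = 0.5              # independent ICP measurement noise, mmHg
    gap_schedule: list[tuple[float, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cpp_mean is None:
            self.cpp_mean = self.true_opt
        if self.cpp_min is None:
            self.cpp_min = self.true_opt - 15.0
        if self.cpp_max is None:
            self.cpp_max = self.true_opt + 15.0
        if self.prx_curve is None:
            a = self.prx_curvature
            self.prx_curve = (a, -2.0 * a * self.true_opt,
                              self.prx_floor + a * self.true_opt ** 2)
        if not (0.0 <= self.cpp_min < self.cpp_max <= 150.0):
            raise PatientSpecError(
                f"CPP bounds [{self.cpp_min}, {self.cpp_max}] outside the "
                "physiological range 0-150 mmHg")
        if self.duration <= 0:
            raise PatientSpecError("duration must be positive")
        # the declared optimum must minimize the correlation curve on the bounds
        grid = np.linspace(self.cpp_min, self.cpp_max, 301)
        if self.rho(self.true_opt) > self.rho(grid).min() + 1e-9:
            raise PatientSpecError("prx_curve is not minimized at true_opt")

    def rho(self, cpp):
        """Target ABP-ICP correlation at a given CPP, clipped to +/-1."""
        a, b, c = self.prx_curve
        return np.clip((a * cpp + b) * cpp + c, -1.0, 1.0)


def _standardize(x: np.ndarray) -> np.ndarray:
    x = x - x.mean()
    s = x.std()
    return x / s if s > 0 else x


def _ar1(rng: np.random.Generator, n: int, phi: float) -> np.ndarray:
    """Unit-ish variance AR(1) draw; phi = 0 reduces to white noise."""
    w = rng.standard_normal(n)
    if phi == 0.0:
        return w
    out = np.empty(n)
    out[0] = w[0]
    scale = np.sqrt(1.0 - phi * phi)
    for i in range(1, n):
        out[i] = phi * out[i - 1] + scale * w[i]
    return out


def _bounded_walk(rng: np.random.Generator, n: int, start: float, sd: float,
                  lo: float, hi: float) -> np.ndarray:
    """Random walk reflected into [lo, hi]."""
    out = np.empty(n)
    v = start
    for i in range(n):
        out[i] = v
        v += rng.normal(0.0, sd)
        while v < lo or v > hi:   # reflect
            if v < lo:
                v = 2 * lo - v
            if v > hi:
                v = 2 * hi - v
    return out


def simulate_patient(spec: VirtualPatientSpec) -> tuple[SampledSeries, SampledSeries]:
    """Generate a (ABP, ICP) pair of 10-s series per the specification.

    Inside every 5-min block the standardized ICP fluctuation is
    ``rho * a + sqrt(1 - rho^2) * e`` with ``a`` the standardized ABP
    slow-wave and ``e`` an orthogonalized unit-variance innovation, so the
    within-block sample correlation equals ``rho(CPP)`` exactly (up to the
    added measurement noise).  Gaps are applied last, leaving the ground
    truth defined inside them.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration / 10.0))
    n_blocks = (n + BLOCK - 1) // BLOCK

    cpp_b = _bounded_walk(rng, n_blocks, spec.cpp_mean, spec.cpp_drift_sd,
                          spec.cpp_min, spec.cpp_max)
    icp_b = spec.icp_baseline + np.cumsum(
        np.concatenate([[0.0], rng.normal(0.0, spec.icp_drift_sd, n_blocks - 1)]))
    icp_b = np.clip(icp_b, 2.0, 40.0)

    abp = np.empty(n)
    icp = np.empty(n)
    wave_a = _ar1(rng, n, spec.wave_ar1)
    wave_e = _ar1(rng, n, spec.wave_ar1)
    for b in range(n_blocks):
        i0, i1 = b * BLOCK, min((b + 1) * BLOCK, n)
        m = i1 - i0
        if m < 3:
            abp[i0:i1] = cpp_b[b] + icp_b[b]
            icp[i0:i1] = icp_b[b]
            continue
        a = _standardize(wave_a[i0:i1])
        e = wave_e[i0:i1]
        e = e - (e @ a) / max(a @ a, 1e-12) * a     # orthogonalize against a
        e = _standardize(e)
        rho = float(spec.rho(cpp_b[b]))
        link = rho * a + np.sqrt(max(0.0, 1.0 - rho * rho)) * e
        abp[i0:i1] = cpp_b[b] + icp_b[b] + spec.wave_sd * a
        icp[i0:i1] = (icp_b[b] + spec.icp_wave_sd * link
                      + spec.noise_sd * rng.standard_normal(m))
    abp = np.maximum(abp, 0.0)
    icp = np.maximum(icp, 0.0)

    valid = np.ones(n, dtype=bool)
    for start, length in spec.gap_schedule:
        j0 = max(0, int(start // 10))
        j1 = min(n, int((start + length) // 10))
        valid[j0:j1] = False

    abp_s = SampledSeries(abp, 10.0, valid=valid.copy())
    icp_s = SampledSeries(icp, 10.0, valid=valid.copy())
    return abp_s, icp_s
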