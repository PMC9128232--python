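"""Periodometry: fundamental-period estimation by harmonic regression.

For a candidate period tau, the minute-binned series Y(t) is regressed by
ordinary least squares on {1, cos(2*pi*t/tau), sin(2*pi*t/tau)}; the
quadrature pair gives the amplitude A = sqrt(beta_cos^2 + beta_sin^2) at that
period.  The zero-amplitude F-test compares the full fit against the
intercept-only model:

    F = ((SSE_reduced - SSE_full)/2) / (SSE_full/(n-3))  ~  F(2, n-3)

under the null of no oscillation at tau.  Frequency decomposition scans the
Fourier periods of the record length inside a near-24-h search window,
refines the amplitude maximum on a fine grid, and then tests the discrete
harmonics tau/2, tau/3, tau/4 of the selected fundamental.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import InsufficientDataError, WheelRecording

__all__ = [
    "HarmonicFit",
    "PeriodogramResult",
    "harmonic_regression",
    "zero_amplitude_ftest",
    "frequency_decomposition",
]

#: relative SSE below which a fit is treated as numerically perfect
_DEGENERATE_RTOL = 1e-12


def as_series(rec, bin_minutes: int = 1) -> tuple[np.ndarray, np.ndarray, float]:
    """Adapter: (values, bin-midpoint hours, ZT/CT offset hours) from either a
    :class:`WheelRecording` or a plain numeric sequence (useful for fitting
    exact analytic signals that are not integer counts)."""
    if isinstance(rec, WheelRecording):
        rec.require_complete()
        y = np.asarray(rec.counts, dtype=float)
        return y, rec.time_hours(), rec.t0_offset_minutes / 60.0
    y = np.asarray(rec, dtype=float)
    t = (np.arange(y.size) + 0.5) * bin_minutes / 60.0
    return y, t, 0.0


@dataclass
class HarmonicFit:
    """OLS harmonic fit of a count series at one candidate period."""

    tau_hours: float
    intercept: float
    beta_cos: float
    beta_sin: float
    amplitude: float
    sse_full: float
    sse_reduced: float
    n_obs: int
    f_stat: float = field(default=np.nan)
    p_value: float = field(default=np.nan)


@dataclass
class PeriodogramResult:
    """Amplitude spectrum over the candidate grid and the selected fundamental."""

    fits: list[HarmonicFit]
    fundamental_tau: float
    fundamental_significant: bool
    harmonics_tested: list[tuple[float, bool]]  # (tau/k, significant)

    @property
    def taus(self) -> np.ndarray:
        return np.array([f.tau_hours for f in self.fits])

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([f.amplitude for f in self.fits])


def _scan(y: np.ndarray, t_hours: np.ndarray, taus: np.ndarray) -> list[HarmonicFit]:
    """Vectorised OLS of y on {1, cos, sin} for every tau in *taus*."""
    n = y.size
    sy = float(y.sum())
    syy = float(y @ y)
    ybar = sy / n
    sse_reduced = syy - n * ybar * ybar
    fits: list[HarmonicFit] = []
    for chunk in np.array_split(taus, max(1, len(taus) // 64)):
        if chunk.size == 0:
            continue
        w = 2.0 * np.pi / chunk[:, None]            # (m, 1)
        c = np.cos(w * t_hours[None, :])            # (m, n)
        s = np.sin(w * t_hours[None, :])
        sc = c.sum(axis=1)
        ss_ = s.sum(axis=1)
        scc = np.einsum("ij,ij->i", c, c)
        sss = np.einsum("ij,ij->i", s, s)
        scs = np.einsum("ij,ij->i", c, s)
        syc = c @ y
        sys_ = s @ y
        for i, tau in enumerate(chunk):
            xtx = np.array([
                [n, sc[i], ss_[i]],
                [sc[i], scc[i], scs[i]],
                [ss_[i], scs[i], sss[i]],
            ])
            xty = np.array([sy, syc[i], sys_[i]])
            coef = np.linalg.solve(xtx, xty)
            sse_full = syy - coef @ xty
            sse_full = max(sse_full, 0.0)
            fits.append(HarmonicFit(
                tau_hours=float(tau),
                intercept=float(coef[0]),
                beta_cos=float(coef[1]),
                beta_sin=float(coef[2]),
                amplitude=float(np.hypot(coef[1], coef[2])),
                sse_full=float(sse_full),
                sse_reduced=float(sse_reduced),
                n_obs=n,
            ))
    return fits


def harmonic_regression(rec, tau: float, bin_minutes: int = 1) -> HarmonicFit:
    """Fit the single-period harmonic model at *tau* (hours) and attach the
    zero-amplitude F-test.

    *rec* may be a :class:`WheelRecording` or a plain series (then
    *bin_minutes* gives its sampling).  Requires a complete record spanning
    at least two full cycles of tau.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    y, t, _ = as_series(rec, bin_minutes)
    if y.size == 0:
        raise InsufficientDataError("empty series")
    duration = t[-1] + t[0]
    if duration < 2 * tau:
        raise InsufficientDataError(
            f"record spans {duration:.1f} h < 2 cycles of tau={tau} h"
        )
    fit = _scan(y, t, np.array([tau]))[0]
    fit.f_stat, fit.p_value = zero_amplitude_ftest(fit)
    return fit


def zero_amplitude_ftest(fit: HarmonicFit) -> tuple[float, float]:
    """F-test of the null hypothesis that the amplitude at fit.tau_hours is zero.

    Degenerate exact fits (SSE_full numerically zero with positive amplitude)
    are reported as (inf, 0).
    """
    n = fit.n_obs
    if n <= 3:
        raise InsufficientDataError("zero-amplitude F-test needs n > 3")
    scale = fit.sse_reduced if fit.sse_reduced > 0 else 1.0
    if fit.sse_full <= _DEGENERATE_RTOL * scale:
        # exact fit; distinguish a perfectly-explained oscillation (p=0)
        # from a constant series where there is nothing to explain (p=1)
        if fit.sse_reduced - fit.sse_full > _DEGENERATE_RTOL * scale:
            return float("inf"), 0.0
        return 0.0, 1.0
    f = ((fit.sse_reduced - fit.sse_full) / 2.0) / (fit.sse_full / (n - 3))
    f = max(f, 0.0)
    p = float(stats.f.sf(f, 2, n - 3))
    return float(f), p


def _fourier_periods(duration_hours: float, window: tuple[float, float]) -> np.ndarray:
    """Fourier periods T/k of the record length inside the search window,
    in decreasing order of tau."""
    lo, hi = window
    k_min = int(np.ceil(duration_hours / hi))
    k_max = int(np.floor(duration_hours / lo))
    ks = np.arange(max(1, k_min), k_max + 1)
    taus = duration_hours / ks
    return taus[(taus >= lo) & (taus <= hi)]


def frequency_decomposition(
    rec,
    window: tuple[float, float] = (20.0, 28.0),
    refine_step: float = 0.01,
    alpha: float = 0.05,
    n_harmonics: int = 3,
    bin_minutes: int = 1,
) -> PeriodogramResult:
    """Identify the fundamental period and test its discrete harmonics.

    Two-stage search: harmonic regression at the Fourier periods of the
    record length intersected with *window*, then a refined grid of spacing
    *refine_step* spanning the interval between the coarse maximum's
    neighbouring Fourier periods.  The fundamental is the amplitude
    maximiser (ties broken toward the smallest tau); harmonics tau/2 ...
    tau/(n_harmonics+1) are each tested with the zero-amplitude F-test at
    level *alpha*.
    """
    if refine_step <= 0:
        raise ValueError("refine_step must be positive")
    y, t, _ = as_series(rec, bin_minutes)
    T = float(t[-1] + t[0])
    lo, hi = window
    if not (0 < lo < hi):
        raise ValueError("invalid search window")
    hi = min(hi, T / 2.0)  # need >= 2 cycles
    if hi <= lo:
        raise ValueError("record too short for the search window")

    coarse_taus = _fourier_periods(T, (lo, hi))
    if coarse_taus.size == 0:
        coarse_taus = np.array([(lo + hi) / 2.0])
    coarse = _scan(y, t, coarse_taus)
    amps = np.array([f.amplitude for f in coarse])
    best = int(np.argmax(amps))
    k_best = round(T / coarse[best].tau_hours)
    ref_lo = max(lo, T / (k_best + 1))
    ref_hi = min(hi, T / (k_best - 1)) if k_best > 1 else hi
    n_steps = int(np.floor((ref_hi - ref_lo) / refine_step))
    refined_taus = ref_lo + refine_step * np.arange(n_steps + 1)
    fits = _scan(y, t, refined_taus)

    # tie-break: smallest tau among (numerically equal) maxima
    f_amps = np.array([f.amplitude for f in fits])
    max_amp = f_amps.max()
    idx = int(np.flatnonzero(f_amps >= max_amp * (1 - 1e-12))[0])
    fund = fits[idx]
    fund.f_stat, fund.p_value = zero_amplitude_ftest(fund)

    harmonics: list[tuple[float, bool]] = []
    for k in range(2, 2 + n_harmonics):
        h_tau = fund.tau_hours / k
        h_fit = _scan(y, t, np.array([h_tau]))[0]
        _, p = zero_amplitude_ftest(h_fit)
        harmonics.append((h_tau, bool(p < alpha)))

    return PeriodogramResult(
        fits=fits,
        fundamental_tau=fund.tau_hours,
        fundamental_significant=bool(fund.p_value < alpha),
        harmonics_tested=harmonics,
    )
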