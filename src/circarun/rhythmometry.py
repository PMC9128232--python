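"""Single-component cosinor rhythmometry.

The cosinor model for a series Y(t) at a known period tau is

    Y(t) = M + A*cos(2*pi*(t - phi)/tau) + e(t)

with M the MESOR (rhythm-adjusted mean), A the amplitude (half the
peak-to-trough range of the fitted curve) and phi the acrophase — the
ZT/CT hour at which the fitted curve peaks, reported in [0, tau).  The model
is linearised as M + beta*cos(w t) + gamma*sin(w t), fitted by ordinary
least squares on the minute-binned counts pooled across all retained days,
and the rhythm parameters recovered as A = sqrt(beta^2 + gamma^2),
phi = atan2(gamma, beta)/w.  Standard errors come from the OLS covariance
via the delta method.  Goodness of fit is checked with the Wald-Wolfowitz
runs test on the residual signs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import InsufficientDataError, ValidationError, WheelRecording
from .periodometry import HarmonicFit, as_series, zero_amplitude_ftest

__all__ = ["CosinorFit", "cosinor_fit", "runs_test", "rhythm_parameters_table",
           "runs_pmf"]


@dataclass
class CosinorFit:
    """Cosinor parameter estimates for one subject at its fundamental period."""

    subject_id: str
    tau_hours: float
    mesor: float
    amplitude: float
    acrophase_hours: float
    se_mesor: float
    se_amplitude: float
    se_acrophase: float
    residuals: np.ndarray
    n_runs: int
    runs_p: float
    f_stat: float
    p_value: float
    sse_full: float
    sse_reduced: float

    @property
    def n_obs(self) -> int:
        return len(self.residuals)


def cosinor_fit(rec, tau: float, bin_minutes: int = 1) -> CosinorFit:
    """Fit the single-component cosinor at period *tau* (hours).

    Time is measured from ZT0 (LD) or CT0 (aligned DD) using the recording's
    ``t0_offset_minutes``, so the acrophase is directly a ZT/CT latency to
    peak.  *rec* may also be a plain series sampled at *bin_minutes*.
    Requires at least two full cycles of tau.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    y, t, t0_hours = as_series(rec, bin_minutes)
    duration = float(t[-1] + t[0])
    if duration < 2 * tau:
        raise InsufficientDataError(
            f"record spans {duration:.1f} h < 2 cycles of tau={tau} h"
        )
    t = t - t0_hours
    w = 2.0 * np.pi / tau
    X = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    n = y.size
    sse_full = float(resid @ resid)
    sse_reduced = float(((y - y.mean()) ** 2).sum())

    mesor, beta, gamma = (float(v) for v in coef)
    amplitude = math.hypot(beta, gamma)
    acrophase = (math.atan2(gamma, beta) / w) % tau

    sigma2 = sse_full / (n - 3) if n > 3 else float("nan")
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se_mesor = math.sqrt(cov[0, 0])
    if amplitude > 0:
        gA = np.array([0.0, beta / amplitude, gamma / amplitude])
        se_amplitude = math.sqrt(float(gA @ cov @ gA))
        # d(phi)/d(beta,gamma) in hours: phi = atan2(gamma, beta)/w
        gP = np.array([0.0, -gamma, beta]) / (amplitude**2 * w)
        se_acrophase = math.sqrt(float(gP @ cov @ gP))
    else:
        se_amplitude = math.sqrt(float(cov[1, 1] + cov[2, 2]) / 2.0)
        se_acrophase = float("inf")

    n_runs, runs_p = runs_test(resid)

    hf = HarmonicFit(
        tau_hours=tau, intercept=mesor, beta_cos=beta, beta_sin=gamma,
        amplitude=amplitude, sse_full=sse_full, sse_reduced=sse_reduced,
        n_obs=n,
    )
    f_stat, p_value = zero_amplitude_ftest(hf)

    subject_id = rec.subject_id if isinstance(rec, WheelRecording) else "series"
    return CosinorFit(
        subject_id=subject_id,
        tau_hours=tau,
        mesor=mesor,
        amplitude=amplitude,
        acrophase_hours=acrophase,
        se_mesor=se_mesor,
        se_amplitude=se_amplitude,
        se_acrophase=se_acrophase,
        residuals=resid,
        n_runs=n_runs,
        runs_p=runs_p,
        f_stat=f_stat,
        p_value=p_value,
        sse_full=sse_full,
        sse_reduced=sse_reduced,
    )


def runs_pmf(n_pos: int, n_neg: int) -> np.ndarray:
    """Exact Wald-Wolfowitz run-count distribution: ``pmf[r]`` is the
    probability of exactly r runs in a random arrangement of n_pos positive
    and n_neg negative signs (index 0 and 1 unused below r=2)."""
    n = n_pos + n_neg
    total = math.comb(n, n_pos)
    pmf = np.zeros(n + 1)
    for k in range(1, min(n_pos, n_neg) + 1):
        pmf[2 * k] = 2 * math.comb(n_pos - 1, k - 1) * math.comb(n_neg - 1, k - 1) / total
    for k in range(1, min(n_pos, n_neg) + 1):
        r = 2 * k + 1
        if r <= n:
            pmf[r] = (
                math.comb(n_pos - 1, k - 1) * math.comb(n_neg - 1, k)
                + math.comb(n_pos - 1, k) * math.comb(n_neg - 1, k - 1)
            ) / total
    return pmf


def runs_test(residuals: Sequence[float], exact_max_n: int = 20) -> tuple[int, float]:
    """Wald-Wolfowitz runs test on residual signs.

    Exact zeros are dropped before forming the sign sequence (the standard
    treatment; ties are common with integer counts).  The two-sided p-value
    is 2*min(lower tail, upper tail) of the run count, from exact
    enumeration when the number of signed residuals is <= *exact_max_n* and
    from the normal approximation with continuity correction otherwise.
    When every residual shares one sign the conditional run-count
    distribution is degenerate; the unconditional sign-pattern probability
    2^(1-n) is reported instead.
    """
    r = np.asarray(residuals, dtype=float)
    signs = np.sign(r)
    signs = signs[signs != 0]
    n = signs.size
    if n < 2:
        raise InsufficientDataError("runs test needs >= 2 nonzero residuals")
    n_pos = int((signs > 0).sum())
    n_neg = n - n_pos
    n_runs = int(1 + (signs[1:] != signs[:-1]).sum())

    if n_pos == 0 or n_neg == 0:
        return n_runs, min(1.0, 2.0 ** (1 - n))

    if n <= exact_max_n:
        pmf = runs_pmf(n_pos, n_neg)
        lower = float(pmf[: n_runs + 1].sum())
        upper = float(pmf[n_runs:].sum())
        p = min(1.0, 2.0 * min(lower, upper))
        return n_runs, p

    mu = 1.0 + 2.0 * n_pos * n_neg / n
    var = 2.0 * n_pos * n_neg * (2.0 * n_pos * n_neg - n) / (n**2 * (n - 1))
    if var <= 0:
        return n_runs, 1.0
    # continuity correction toward the mean
    z = (abs(n_runs - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * float(stats.norm.sf(z)))
    return n_runs, p


def rhythm_parameters_table(
    fits: Iterable[CosinorFit],
    metadata: pd.DataFrame,
    alpha_fit: float = 0.05,
) -> pd.DataFrame:
    """Collapse per-subject cosinor fits into long-format study-table rows.

    *metadata* is indexed (or indexable) by subject_id with columns genotype,
    sex, age_group, condition.  Each subject contributes three rows (mesor,
    amplitude, acrophase).  Subjects whose runs test rejects at *alpha_fit*
    are flagged ``poor_fit`` but retained.
    """
    meta = metadata.set_index("subject_id") if "subject_id" in metadata.columns else metadata
    rows = []
    seen: set[str] = set()
    for fit in fits:
        if fit.subject_id in seen:
            raise ValidationError(f"duplicate subject {fit.subject_id}")
        seen.add(fit.subject_id)
        m = meta.loc[fit.subject_id]
        for measure, value in (
            ("mesor", fit.mesor),
            ("amplitude", fit.amplitude),
            ("acrophase", fit.acrophase_hours),
        ):
            rows.append({
                "subject_id": fit.subject_id,
                "genotype": m["genotype"],
                "sex": m["sex"],
                "age_group": m["age_group"],
                "condition": m["condition"],
                "outcome_measure": measure,
                "value": value,
                "poor_fit": bool(fit.runs_p < alpha_fit),
            })
    cols = ["subject_id", "genotype", "sex", "age_group", "condition",
            "outcome_measure", "value", "poor_fit"]
    return pd.DataFrame(rows, columns=cols)
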