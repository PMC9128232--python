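"""Synthetic wheel-running actigraphy generator.

Emulates minute-binned home-cage wheel-revolution recordings of mice under a
12:12 light:dark schedule (LD) or constant darkness (DD): a near-24-h
sinusoidal rate, rectified at zero, optionally suppressed during the light
phase (masking), with bursty negative-binomial counts per minute.

The rate model is

    lambda(t) = max(0, M + A * cos(2*pi*(t - phi)/tau)) * mask(t)

with M the MESOR (counts/min), A the amplitude, phi the acrophase (ZT/CT hour
of peak rate), tau the period in hours, and mask(t) = light_mask during the
light phase (ZT [0, 12)) of LD recordings, 1 otherwise.  Counts per bin are
negative binomial with mean lambda and variance lambda + lambda^2/dispersion
(Poisson in the dispersion -> infinity limit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .io import MINUTES_PER_DAY, WheelRecording

__all__ = [
    "SimulationParams",
    "CohortJitter",
    "simulate_recording",
    "simulate_cohort",
    "genotype_presets",
    "square_wave_recording",
    "expected_mean_rate",
]


@dataclass
class SimulationParams:
    """Generative parameters for one synthetic recording.

    ``amplitude`` may exceed ``mesor``: the rate is rectified at zero rather
    than constrained, which produces the crisp activity offsets real wheel
    records show.
    """

    mesor: float = 20.0            # counts per minute
    amplitude: float = 15.0        # counts per minute
    acrophase_hours: float = 18.0  # ZT/CT hour of peak rate
    tau_hours: float = 24.0
    n_days: int = 10
    condition: str = "LD"
    light_mask: float = 0.15       # multiplicative rate suppression, light phase
    dispersion: float = 5.0        # NB overdispersion; math.inf -> Poisson
    seed: int = 0

    def validate(self) -> None:
        if self.mesor < 0 or self.amplitude < 0:
            raise ValueError("mesor and amplitude must be nonnegative")
        if not (0 < self.tau_hours):
            raise ValueError("tau_hours must be positive")
        if not (0 <= self.acrophase_hours < self.tau_hours):
            raise ValueError("acrophase_hours must lie in [0, tau)")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.condition not in ("LD", "DD"):
            raise ValueError("condition must be LD or DD")
        if not (0.0 <= self.light_mask <= 1.0):
            raise ValueError("light_mask must lie in [0, 1]")
        if not (self.dispersion > 0):
            raise ValueError("dispersion must be positive")
        for name in ("mesor", "amplitude", "acrophase_hours", "tau_hours", "light_mask"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def _rate(params: SimulationParams, t_hours: np.ndarray) -> np.ndarray:
    """Rectified, masked cosine rate (counts/min) at times *t_hours* from ZT0/CT0."""
    lam = params.mesor + params.amplitude * np.cos(
        2.0 * np.pi * (t_hours - params.acrophase_hours) / params.tau_hours
    )
    lam = np.maximum(lam, 0.0)
    if params.condition == "LD":
        zt = t_hours % 24.0
        lam = np.where(zt < 12.0, lam * params.light_mask, lam)
    return lam


def expected_mean_rate(params: SimulationParams, n_grid: int = 200_000) -> float:
    """Time-average of the rectified masked rate, by numerical integration
    over the full simulated span (independent check for the sampler)."""
    t = (np.arange(n_grid) + 0.5) * (params.n_days * 24.0 / n_grid)
    return float(_rate(params, t).mean())


def _sample_counts(lam: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    if math.isinf(dispersion):
        return rng.poisson(lam)
    # NB(r, p) with mean lam: p = r / (r + lam); lam = 0 -> p = 1 -> count 0
    p = dispersion / (dispersion + lam)
    return rng.negative_binomial(dispersion, p)


def simulate_recording(
    params: SimulationParams,
    subject_id: str = "sim",
    genotype: str = "custom",
    sex: str = "F",
    age_group: str = "young",
) -> WheelRecording:
    """Draw one minute-binned recording from the rate model.

    The recording starts at ZT0 (LD) or CT0 (DD reference), i.e.
    ``t0_offset_minutes = 0``.  Identical parameters and seed give an
    identical series.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_days * MINUTES_PER_DAY
    t_hours = (np.arange(n) + 0.5) / 60.0
    lam = _rate(params, t_hours)
    counts = _sample_counts(lam, params.dispersion, rng).astype(np.int64)
    return WheelRecording(
        subject_id=subject_id,
        genotype=genotype,
        sex=sex,
        age_group=age_group,
        condition=params.condition,
        counts=counts,
        bin_minutes=1,
        lights_on_clock="07:00" if params.condition == "LD" else None,
        t0_offset_minutes=0.0,
    )


@dataclass
class CohortJitter:
    """Between-animal variability applied on top of a group's parameters.

    MESOR and amplitude are jittered multiplicatively (lognormal with the
    given sigma on the log scale); the acrophase receives additive
    wrapped-normal jitter in hours.  Zero sigmas give identical expected
    profiles for every subject in a group.
    """

    mesor_sigma: float = 0.15
    amplitude_sigma: float = 0.15
    acrophase_sd_hours: float = 0.5


def simulate_cohort(
    design: Mapping[str, tuple[SimulationParams, int]],
    seed: int = 0,
    jitter: CohortJitter | None = None,
    age_group: str = "young",
) -> list[WheelRecording]:
    """Simulate a cohort: ``design`` maps genotype -> (params, n_subjects).

    Per-subject seeds are spawned deterministically from the master seed, so
    the same master seed reproduces the cohort bit for bit.  Sexes alternate
    within each group (balanced cohorts).
    """
    if jitter is None:
        jitter = CohortJitter()
    recs: list[WheelRecording] = []
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(sum(n for _, n in design.values())))
    for genotype, (params, n_subjects) in design.items():
        if n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for i in range(n_subjects):
            child = next(children)
            rng = np.random.default_rng(child)
            m = params.mesor * math.exp(rng.normal(0.0, jitter.mesor_sigma)) \
                if jitter.mesor_sigma > 0 else params.mesor
            a = params.amplitude * math.exp(rng.normal(0.0, jitter.amplitude_sigma)) \
                if jitter.amplitude_sigma > 0 else params.amplitude
            phi = (params.acrophase_hours + (
                rng.normal(0.0, jitter.acrophase_sd_hours)
                if jitter.acrophase_sd_hours > 0 else 0.0
            )) % params.tau_hours
            sub_seed = int(rng.integers(0, 2**31 - 1))
            p = replace(params, mesor=m, amplitude=a, acrophase_hours=phi,
                        seed=sub_seed)
            recs.append(simulate_recording(
                p,
                subject_id=f"{genotype}_{i:02d}",
                genotype=genotype,
                sex="F" if i % 2 == 0 else "M",
                age_group=age_group,
            ))
    return recs


# ---------------------------------------------------------------------------
# Genotype presets.  Magnitudes are synthetic package defaults chosen to give
# realistic C57BL/6J-scale wheel output; only the *directions* of the group
# contrasts (period lengthening, amplitude loss, hyper/hypoactivity) emulate
# the study designs these panels stand in for.
# ---------------------------------------------------------------------------

def _p(**kw) -> SimulationParams:
    params = SimulationParams(**kw)
    params.validate()
    return params


def genotype_presets(strain_design: str) -> dict[str, dict[str, SimulationParams]]:
    """Preset simulation parameters per genotype and lighting condition.

    ``rcan1_panel``: wild-type (WT) with knockout (KO), and non-transgenic
    (NTG) with overexpressing transgenic (TG) littermate pairs.  KO and TG
    free-run with a longer endogenous period than their controls; TG has
    lower MESOR/amplitude than NTG in both conditions; KO is hyperactive in
    DD (higher MESOR/amplitude) but hypoactive in LD.

    ``dp16_panel``: trisomic Dp16 below WT on MESOR/amplitude with the
    Dp16_Rcan1_2N (gene-dose corrected) group intermediate.

    All magnitudes are synthetic defaults, not measured values.
    """
    # Baseline waveform: M=7, A=21 counts/min with the rate rectified at
    # zero gives a ~14.6-h active phase, a ~9.4-h quiescent rest phase and
    # ~15k revolutions/day at a 28 revs/min peak -- the shape and scale of
    # young C57BL/6J wheel output.  Group effects are
    # applied as multiplicative activity scalings (which scale the fitted
    # MESOR and amplitude together and leave the waveform shape, hence the
    # acrophase and detected onsets, unchanged) plus period shifts in DD.
    def scaled(factor: float, tau: float, condition: str, n_days: int) -> SimulationParams:
        return _p(mesor=7.0 * factor, amplitude=21.0 * factor,
                  tau_hours=tau, condition=condition, n_days=n_days,
                  acrophase_hours=18.0)

    if strain_design == "rcan1_panel":
        return {
            # controls free-run at 23.7 h; KO and TG free-run longer
            "WT": {"LD": scaled(1.0, 24.0, "LD", 10),
                   "DD": scaled(1.0, 23.7, "DD", 13)},
            "KO": {"LD": scaled(0.8, 24.0, "LD", 10),     # hypoactive in LD
                   "DD": scaled(1.3, 23.9, "DD", 13)},    # hyperactive in DD
            "NTG": {"LD": scaled(1.0, 24.0, "LD", 10),
                    "DD": scaled(1.0, 23.7, "DD", 13)},
            "TG": {"LD": scaled(0.6, 24.0, "LD", 10),     # amplitude 40% below NTG
                   "DD": scaled(0.6, 23.9, "DD", 13)},
        }
    if strain_design == "dp16_panel":
        return {
            "WT": {"LD": scaled(1.0, 24.0, "LD", 14),
                   "DD": scaled(1.0, 23.7, "DD", 14)},
            "Dp16": {"LD": scaled(0.55, 24.0, "LD", 14),
                     "DD": scaled(0.55, 23.8, "DD", 14)},
            "Dp16_Rcan1_2N": {"LD": scaled(0.8, 24.0, "LD", 14),
                              "DD": scaled(0.8, 23.75, "DD", 14)},
        }
    raise ValueError(f"unknown strain design {strain_design!r}")


def square_wave_recording(
    tau_hours: float = 24.0,
    n_days: int = 10,
    high_rate: int = 30,
    onset_hour: float = 12.0,
    alpha_hours: float = 12.0,
    subject_id: str = "square",
    condition: str = "DD",
) -> WheelRecording:
    """Deterministic square-wave activity profile (pure alpha/rho structure).

    Rate is ``high_rate`` counts/min during [onset, onset + alpha_hours) of
    each tau-hour cycle and exactly zero otherwise — the fixture on which
    onset/offset detection has a closed-form right answer.
    """
    n = n_days * MINUTES_PER_DAY
    t_hours = np.arange(n) / 60.0
    phase = (t_hours - onset_hour) % tau_hours
    counts = np.where(phase < alpha_hours, high_rate, 0).astype(np.int64)
    return WheelRecording(
        subject_id=subject_id,
        genotype="custom",
        sex="F",
        age_group="young",
        condition=condition,
        counts=counts,
        bin_minutes=1,
        lights_on_clock="07:00" if condition == "LD" else None,
        t0_offset_minutes=0.0,
    )
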