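"""Free-running (constant-darkness) preprocessing.

A free-running animal's activity drifts relative to the 24-h clock at a rate
set by its endogenous period tau.  This module detects the daily activity
onset and offset, regresses onset time on day number (the slope of that line
is (tau - 24)*60 min/day for a clean free-runner), rescales the time axis
into circadian hours (tau conventional hours per 24 circadian hours) and
phase-shifts it so that the average onset falls at circadian time (CT) 12 —
the conventional phase of activity onset in nocturnal rodents.  The aligned
record supports partitioning each circadian day into the alpha (active,
onset-to-offset) and rho (inactive, offset-to-onset) phases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .io import MINUTES_PER_DAY, InsufficientDataError, WheelRecording

__all__ = [
    "OnsetParams",
    "OnsetSeries",
    "detect_daily_onsets",
    "circadian_hour_length",
    "align_to_ct12",
    "partition_alpha_rho",
]


@dataclass
class OnsetParams:
    """Onset/offset detection settings.

    The threshold is relative (a fraction of the search window's mean rate),
    so detection is invariant to uniform count scaling.  Defaults follow
    standard actography practice: 15-min moving-average smoothing, onset =
    first bin sustained above 25% of the daily mean rate for >= 30 min after
    >= 60 min of quiescence.
    """

    threshold_fraction: float = 0.25
    sustain_minutes: int = 30
    quiescence_minutes: int = 60
    smooth_minutes: int = 15


@dataclass
class OnsetSeries:
    """Per-day activity onsets/offsets and the onset regression line."""

    onset_minutes: dict[int, float]      # day index -> minutes from record start
    offset_minutes: dict[int, float]
    regression_slope: float              # minutes/day; (tau-24)*60 for clean data
    regression_intercept: float
    days_excluded: list[int]
    mean_onset_circadian: float | None = None  # CT hours, set by align_to_ct12

    @property
    def days(self) -> list[int]:
        return sorted(self.onset_minutes)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    if window % 2 == 0:
        window += 1
    kernel = np.ones(window) / window
    pad = window // 2
    xp = np.pad(x.astype(float), pad, mode="edge")
    return np.convolve(xp, kernel, mode="valid")


def _find_onset_offset(
    rate: np.ndarray,
    smoothed: np.ndarray,
    lo: int,
    hi: int,
    p: OnsetParams,
    bin_minutes: int,
) -> tuple[int | None, int | None]:
    """Earliest qualifying onset and its bout offset inside window [lo, hi)."""
    window_rate = rate[lo:hi]
    mean_rate = window_rate.mean()
    if mean_rate <= 0:
        return None, None
    thr = p.threshold_fraction * mean_rate
    sustain = max(1, p.sustain_minutes // bin_minutes)
    quiesce = max(1, p.quiescence_minutes // bin_minutes)
    smooth_half = max(1, p.smooth_minutes // bin_minutes)

    above = smoothed >= thr
    n = len(rate)
    i = lo
    while i < hi:
        if above[i] and (i == 0 or not above[i - 1]):
            # sustained above for >= sustain bins
            end = min(n, i + sustain)
            if end - i == sustain and above[i:end].all():
                # preceded by >= quiesce bins below threshold (or record start)
                start = max(0, i - quiesce)
                if not above[start:i].any():
                    # refine to the first raw bin at/above threshold nearby
                    j0 = max(lo, i - smooth_half)
                    j1 = min(hi, i + smooth_half + 1)
                    cand = np.flatnonzero(rate[j0:j1] >= thr)
                    onset = j0 + int(cand[0]) if cand.size else i
                    offset = _find_offset(rate, above, onset, thr, sustain, quiesce, n)
                    return onset, offset
        i += 1
    return None, None


def _find_offset(
    rate: np.ndarray,
    above: np.ndarray,
    onset: int,
    thr: float,
    sustain: int,
    quiesce: int,
    n: int,
) -> int | None:
    """End of the activity bout starting at *onset*: the last above-threshold
    bin before a quiescence-length gap (searched within one day of onset)."""
    limit = min(n, onset + MINUTES_PER_DAY)
    j = onset
    last_above = onset
    while j < limit:
        if above[j] or rate[j] >= thr:
            last_above = j
            j += 1
            continue
        # below threshold: is this a real gap?
        gap_end = min(n, j + quiesce)
        if not (above[j:gap_end].any() or (rate[j:gap_end] >= thr).any()):
            break
        j += 1
    # refine to the last raw bin at/above threshold (smoothing widens bouts)
    while last_above > onset and rate[last_above] < thr:
        last_above -= 1
    if last_above >= n - 1:
        return None  # bout censored by the record end: no real offset
    return last_above


def detect_daily_onsets(
    rec: WheelRecording, params: OnsetParams | None = None
) -> OnsetSeries:
    """Detect per-day activity onsets/offsets and regress onset on day index.

    Two passes: calendar-day windows give initial candidates; a straight
    line through them predicts each day's onset, and the search is repeated
    in a one-day window centred on the prediction so that onsets drifting
    across calendar-day boundaries (tau far from 24 h) are still assigned to
    the right day.  Days without a detectable onset (e.g. zero activity) are
    recorded in ``days_excluded`` and skipped by the regression.
    """
    if params is None:
        params = OnsetParams()
    rec.require_complete()
    bpd = rec.bins_per_day
    n_days = rec.n_days
    if n_days < 5:
        raise InsufficientDataError("onset detection needs >= 5 analyzable days")
    rate = np.asarray(rec.counts, dtype=float) / rec.bin_minutes
    smoothed = _moving_average(rate, max(1, params.smooth_minutes // rec.bin_minutes))

    # pass 1: calendar-day windows
    onsets: dict[int, float] = {}
    offsets: dict[int, float] = {}
    for d in range(n_days):
        onset, offset = _find_onset_offset(
            rate, smoothed, d * bpd, (d + 1) * bpd, params, rec.bin_minutes
        )
        if onset is not None:
            onsets[d] = onset * rec.bin_minutes
            if offset is not None:
                offsets[d] = offset * rec.bin_minutes

    def _regress(onset_map: dict[int, float]):
        # regression of within-day onset time on day index; the slope is the
        # daily drift, (tau - 24 h) * 60 for a clean free-runner
        days = np.array(sorted(onset_map))
        rel = np.array([onset_map[d] - MINUTES_PER_DAY * d for d in days])
        return stats.linregress(days, rel)

    if len(onsets) >= 3:
        lr = _regress(onsets)
        # pass 2: prediction-centred windows
        onsets2: dict[int, float] = {}
        offsets2: dict[int, float] = {}
        for d in range(n_days):
            pred = MINUTES_PER_DAY * d + lr.intercept + lr.slope * d
            lo = int(round(pred / rec.bin_minutes)) - bpd // 2
            hi = lo + bpd
            lo = max(0, lo)
            hi = min(rec.n_bins, hi)
            if hi - lo < bpd // 2:
                continue
            onset, offset = _find_onset_offset(
                rate, smoothed, lo, hi, params, rec.bin_minutes
            )
            if onset is not None:
                onsets2[d] = onset * rec.bin_minutes
                if offset is not None:
                    offsets2[d] = offset * rec.bin_minutes
        if len(onsets2) >= len(onsets):
            onsets, offsets = onsets2, offsets2

    if len(onsets) < 3:
        raise InsufficientDataError(
            f"subject {rec.subject_id}: only {len(onsets)} detectable onsets"
        )
    excluded = sorted(set(range(n_days)) - set(onsets))
    if excluded:
        warnings.warn(
            f"subject {rec.subject_id}: days {excluded} have no detectable onset",
            stacklevel=2,
        )
    lr = _regress(onsets)
    return OnsetSeries(
        onset_minutes=dict(onsets),
        offset_minutes=dict(offsets),
        regression_slope=float(lr.slope),
        regression_intercept=float(lr.intercept),
        days_excluded=excluded,
    )


def circadian_hour_length(tau_hours: float) -> float:
    """Duration of one circadian hour in conventional hours: tau / 24."""
    if tau_hours <= 0:
        raise ValueError("tau must be positive")
    return tau_hours / 24.0


def _onset_phases_ct(onsets: OnsetSeries, chl: float) -> np.ndarray:
    """Circadian-minute phase of each detected onset (before CT12 shift)."""
    vals = np.array([onsets.onset_minutes[d] for d in onsets.days])
    return (vals / chl) % MINUTES_PER_DAY


def _circular_mean(phases: np.ndarray, period: float = MINUTES_PER_DAY) -> float:
    ang = phases * 2.0 * np.pi / period
    mean = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
    return float((mean * period / (2.0 * np.pi)) % period)


def align_to_ct12(
    rec: WheelRecording,
    onsets: OnsetSeries,
    tau_hours: float,
    truncate_days: bool = False,
) -> WheelRecording:
    """Rescale a free-running record into circadian time anchored at CT12.

    The time axis is divided by the circadian-hour length (tau/24) and
    shifted so that the circular mean of the detected onset phases maps to
    CT12.  Counts are redistributed into circadian-minute bins by
    interpolating the cumulative count curve at the mapped bin edges, which
    conserves the total count exactly.  With ``truncate_days`` the output is
    cut to whole circadian days starting at CT0 (partial edge days dropped,
    so totals are then smaller).
    """
    if not (20.0 < tau_hours < 28.0):
        raise ValueError(
            f"tau={tau_hours} h outside (20, 28); upstream period estimate suspect"
        )
    rec.require_complete()
    chl = circadian_hour_length(tau_hours)
    theta = _circular_mean(_onset_phases_ct(onsets, chl))

    n_min = rec.n_bins * rec.bin_minutes
    # circadian time (minutes) of conventional minute m: m/chl - theta + 720
    ct_start = 0.0 / chl - theta + 720.0
    ct_end = n_min / chl - theta + 720.0
    j0 = int(np.floor(ct_start))
    j1 = int(np.ceil(ct_end))
    edges_ct = np.arange(j0, j1 + 1, dtype=float)
    # inverse map to conventional minutes
    edges_conv = (edges_ct - 720.0 + theta) * chl
    cum = np.concatenate([[0.0], np.cumsum(np.asarray(rec.counts, dtype=float))])
    conv_grid = np.arange(rec.n_bins + 1, dtype=float) * rec.bin_minutes
    cum_at = np.interp(edges_conv, conv_grid, cum)
    counts_ct = np.diff(cum_at)

    t0 = (-j0) % MINUTES_PER_DAY  # CT of output bin b is (b - t0) mod 1440
    out = WheelRecording(
        subject_id=rec.subject_id,
        genotype=rec.genotype,
        sex=rec.sex,
        age_group=rec.age_group,
        condition=rec.condition,
        counts=counts_ct,
        bin_minutes=1,
        lights_on_clock=None,
        t0_offset_minutes=float(t0),
        frame="CT",
        ct_transform={"tau_hours": tau_hours, "chl": chl,
                      "onset_anchor_ct_minutes": theta, "j0": j0},
    )
    onsets.mean_onset_circadian = 12.0
    if truncate_days:
        # bin b has CT 0 when (b - t0) % 1440 == 0  ->  b = t0 (mod 1440)
        start = int(t0 % MINUTES_PER_DAY)
        n_whole = (out.n_bins - start) // MINUTES_PER_DAY
        counts = out.counts[start : start + n_whole * MINUTES_PER_DAY]
        out = replace(out, counts=counts, t0_offset_minutes=0.0)
    return out


def alpha_window_ct(
    onsets: OnsetSeries, tau_hours: float
) -> tuple[float, float]:
    """Alpha-phase window in CT hours implied by the detected onsets/offsets.

    After CT12 alignment the mean onset sits at CT12 by construction; the
    offset is CT12 plus the mean onset-to-offset duration expressed in
    circadian hours.
    """
    chl = circadian_hour_length(tau_hours)
    both = [d for d in onsets.days if d in onsets.offset_minutes]
    if not both:
        raise InsufficientDataError("no days with both onset and offset")
    durations = np.array([
        (onsets.offset_minutes[d] - onsets.onset_minutes[d]) / chl / 60.0
        for d in both
    ])
    return 12.0, 12.0 + float(durations.mean())


def partition_alpha_rho(
    rec_ct: WheelRecording,
    onset_ct_hours: float = 12.0,
    offset_ct_hours: float = 24.0,
) -> pd.DataFrame:
    """Split each whole circadian day into alpha (active) and rho (inactive)
    phase totals.

    The alpha window is CT [onset, offset) (wrapping across CT0 if needed);
    rho is the remainder of the circadian day, computed as day total minus
    alpha so that alpha + rho equals the day total exactly.  ``pct_rho`` is
    100*rho/total, reported as 0 with a flag for days without any activity.
    """
    if rec_ct.frame != "CT":
        raise ValueError("partition_alpha_rho expects a CT-frame recording")
    ct = (np.arange(rec_ct.n_bins) * rec_ct.bin_minutes
          - rec_ct.t0_offset_minutes) % MINUTES_PER_DAY
    ct_h = ct / 60.0
    a, b = onset_ct_hours % 24.0, offset_ct_hours % 24.0
    if a <= b:
        alpha_mask = (ct_h >= a) & (ct_h < b) if a < b else np.zeros_like(ct_h, bool)
        if a == b:  # degenerate window covers the full day by convention
            alpha_mask = np.ones_like(ct_h, dtype=bool)
    else:
        alpha_mask = (ct_h >= a) | (ct_h < b)

    # whole circadian days only, starting at the first CT0 bin
    start = int(rec_ct.t0_offset_minutes % MINUTES_PER_DAY)
    n_days = (rec_ct.n_bins - start) // MINUTES_PER_DAY
    rows = []
    counts = np.asarray(rec_ct.counts, dtype=float)
    for d in range(n_days):
        sl = slice(start + d * MINUTES_PER_DAY, start + (d + 1) * MINUTES_PER_DAY)
        day_counts = counts[sl]
        day_alpha_mask = alpha_mask[sl]
        total = float(day_counts.sum())
        alpha = float(day_counts[day_alpha_mask].sum())
        rho = total - alpha
        zero_day = total == 0
        pct_rho = 0.0 if zero_day else 100.0 * rho / total
        rows.append({
            "day": d, "alpha_counts": alpha, "rho_counts": rho,
            "total": total, "pct_rho": pct_rho, "zero_day": zero_day,
        })
    return pd.DataFrame(rows)
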