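"""Actogram and daily-profile visualization.

All plotting is deterministic given the inputs and style arguments; every
function returns the plotted array(s) alongside writing the figure, so tests
can check pixel-level content without decoding images.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .io import WheelRecording, rebin
from .rhythmometry import CosinorFit

__all__ = ["plot_actogram_heatmap", "plot_profile_with_fit"]


def _group_daily_matrix(
    recordings: Sequence[WheelRecording], bin_minutes: int
) -> np.ndarray:
    mats = []
    n_days = min(r.n_days for r in recordings)
    for rec in recordings:
        r = rebin(rec, bin_minutes) if rec.bin_minutes != bin_minutes else rec
        mats.append(r.daily_matrix()[:n_days])
    return np.mean(mats, axis=0)


def plot_actogram_heatmap(
    recordings: Sequence[WheelRecording],
    path: str | Path | None = None,
    days: tuple[int, int] | None = None,
    bin_minutes: int = 10,
    double_plot: bool = False,
    cmap: str = "viridis",
) -> np.ndarray:
    """Heatmap-style actogram of group-mean wheel revolutions.

    Rows are days, columns time-of-day bins, colour the mean revolutions
    across subjects, normalised per panel to the group maximum.  Returns the
    un-normalised matrix that was drawn.
    """
    recordings = list(recordings)
    if not recordings:
        raise ValueError("empty recording group")
    conditions = {r.condition for r in recordings}
    frames = {r.frame for r in recordings}
    if len(conditions) > 1 or len(frames) > 1:
        raise ValueError("recordings must share lighting condition and frame")
    mat = _group_daily_matrix(recordings, bin_minutes)
    if days is not None:
        mat = mat[days[0] : days[1]]
    shown = np.hstack([mat, np.vstack([mat[1:], np.zeros_like(mat[:1])])]) \
        if double_plot else mat
    if path is not None:
        fig, ax = plt.subplots(figsize=(8, 0.4 * len(shown) + 1.5))
        vmax = shown.max() if shown.max() > 0 else 1.0
        ax.imshow(shown, aspect="auto", cmap=cmap, vmin=0, vmax=vmax,
                  interpolation="nearest")
        hours = 48 if double_plot else 24
        ax.set_xticks(np.linspace(0, shown.shape[1], hours // 6 + 1))
        ax.set_xticklabels([f"{h:.0f}" for h in np.linspace(0, hours, hours // 6 + 1)])
        frame = recordings[0].frame
        ax.set_xlabel("CT (h)" if frame == "CT" else "ZT (h)")
        ax.set_ylabel("day")
        ax.set_title(f"{conditions.pop()} group actogram (n={len(recordings)})")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return mat


def plot_profile_with_fit(
    recordings: Sequence[WheelRecording],
    fits: Sequence[CosinorFit],
    path: str | Path | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hourly mean +/- SEM daily activity profile with the group-mean fitted
    cosine and a 95% band from between-subject fit dispersion.

    Returns (hourly means across subjects, hourly SEM, fitted curve sampled
    hourly).
    """
    recordings = list(recordings)
    fits = list(fits)
    if len(recordings) != len(fits):
        raise ValueError("one cosinor fit per recording required")
    by_id = {f.subject_id for f in fits}
    if {r.subject_id for r in recordings} != by_id:
        raise ValueError("fit subjects do not match recording subjects")

    profiles = []
    for rec in recordings:
        hourly = rebin(rec, 60) if rec.bin_minutes != 60 else rec
        mat = hourly.daily_matrix().astype(float)
        # roll so column 0 is ZT/CT 0
        shift = int(round(hourly.t0_offset_minutes / 60.0)) % 24
        profiles.append(np.roll(mat.mean(axis=0), -shift))
    prof = np.asarray(profiles)
    mean = prof.mean(axis=0)
    sem = prof.std(axis=0, ddof=1) / np.sqrt(len(prof)) if len(prof) > 1 \
        else np.zeros_like(mean)

    hours = np.arange(24) + 0.5
    # per-subject fitted curves are in counts/bin of the fit (minute bins);
    # scale to counts/hour for comparison with hourly means
    scale = 60.0
    curves = np.asarray([
        scale * (f.mesor + f.amplitude * np.cos(
            2 * np.pi * (hours - f.acrophase_hours) / f.tau_hours))
        for f in fits
    ])
    curve = curves.mean(axis=0)
    band = 1.96 * curves.std(axis=0, ddof=1) / np.sqrt(len(curves)) \
        if len(curves) > 1 else np.zeros_like(curve)

    if path is not None:
        fig, ax = plt.subplots(figsize=(7, 4))
        ax.errorbar(hours, mean, yerr=sem, fmt="o", ms=4, capsize=2,
                    label="hourly mean +/- SEM")
        ax.plot(hours, curve, "-", label="mean cosinor fit")
        ax.fill_between(hours, curve - band, curve + band, alpha=0.25,
                        label="95% CI")
        frame = recordings[0].frame
        ax.set_xlabel("CT (h)" if frame == "CT" else "ZT (h)")
        ax.set_ylabel("wheel revolutions / h")
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return mean, sem, curve
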