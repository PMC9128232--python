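"""Core domain types, time conventions, file I/O and preprocessing.

The central container is :class:`WheelRecording`: one animal's wheel-revolution
series in fixed-width time bins (1 min for raw acquisitions) plus the metadata
needed to place every bin on a Zeitgeber-time (ZT, light-entrained) or
circadian-time (CT, free-running) axis.

Time conventions
----------------
ZT0 is lights-on; under a 12:12 light:dark schedule the light phase is
ZT [0, 12) and the dark phase ZT [12, 24), half-open so the two phases
partition each day with no double counting.  ``t0_offset_minutes`` is the
number of minutes between the start of the recording and the first ZT0
(or an arbitrary reference for constant-darkness recordings), so the ZT of
bin *i* is ``((i * bin_minutes) - t0_offset_minutes) mod 1440`` minutes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MINUTES_PER_DAY = 1440

#: sentinel used by the reader for documented gaps; analysis operations reject
#: recordings that still contain it.
MISSING = -1

GENOTYPES = frozenset(
    {"WT", "KO", "TG", "NTG", "Dp16", "Dp16_Rcan1_2N", "custom"}
)
SEXES = frozenset({"F", "M"})
AGE_GROUPS = frozenset({"young", "aged"})
CONDITIONS = frozenset({"LD", "DD"})

#: registered vocabulary of per-subject outcome measures (long-format tables).
OUTCOME_MEASURES = {
    "period_hours",
    "mesor",
    "amplitude",
    "acrophase",
    "total_daily",
    "active_phase_daily",
    "inactive_phase_daily",
    "pct_inactive",
    "alpha_daily",
    "rho_daily",
    "pct_rho",
}


class FormatError(ValueError):
    """Malformed input file (missing column, bad dialect)."""


class ValidationError(ValueError):
    """Semantically invalid data (negative count, unknown level...)."""


class InsufficientDataError(ValueError):
    """Recording too short for the requested operation."""


class InvalidConditionError(ValueError):
    """Operation called on a recording in the wrong lighting condition."""


def register_outcome_measure(name: str) -> None:
    """Add *name* to the registered outcome-measure vocabulary."""
    OUTCOME_MEASURES.add(name)


@dataclass
class WheelRecording:
    """One animal's binned wheel-revolution series plus experimental metadata.

    ``counts`` are nonnegative integers in the conventional-time frame; a
    recording in the circadian frame (``frame='CT'``, produced by CT12
    alignment) may carry fractional counts because source minutes are split
    proportionally across circadian minutes.
    """

    subject_id: str
    genotype: str
    sex: str
    age_group: str
    condition: str
    counts: np.ndarray
    bin_minutes: int = 1
    lights_on_clock: str | None = None
    t0_offset_minutes: float = 0.0
    frame: str = "conventional"  # 'conventional' or 'CT'
    ct_transform: dict | None = None

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValidationError(f"unknown genotype {self.genotype!r}")
        if self.sex not in SEXES:
            raise ValidationError(f"unknown sex {self.sex!r}")
        if self.age_group not in AGE_GROUPS:
            raise ValidationError(f"unknown age_group {self.age_group!r}")
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        if self.frame not in ("conventional", "CT"):
            raise ValidationError(f"unknown frame {self.frame!r}")
        if not (self.bin_minutes > 0 and MINUTES_PER_DAY % self.bin_minutes == 0):
            raise ValidationError("bin_minutes must divide a day")
        if self.condition == "DD" and self.lights_on_clock is not None:
            raise ValidationError("DD recordings have no lights_on_clock semantics")
        arr = np.asarray(self.counts)
        if self.frame == "conventional":
            if not np.issubdtype(arr.dtype, np.integer):
                as_int = arr.astype(np.int64)
                if not np.array_equal(as_int, arr):
                    raise ValidationError(
                        "wheel revolutions are counts; fractional values rejected"
                    )
                arr = as_int
            if np.any((arr < 0) & (arr != MISSING)):
                raise ValidationError("negative counts")
            self.counts = arr.astype(np.int64)
        else:
            self.counts = arr.astype(np.float64)
            if np.any(self.counts < 0):
                raise ValidationError("negative counts in CT frame")

    # -- derived geometry -------------------------------------------------
    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def bins_per_day(self) -> int:
        return MINUTES_PER_DAY // self.bin_minutes

    @property
    def n_days(self) -> int:
        """Number of complete days in the record."""
        return self.n_bins // self.bins_per_day

    @property
    def duration_hours(self) -> float:
        return self.n_bins * self.bin_minutes / 60.0

    @property
    def has_missing(self) -> bool:
        return self.frame == "conventional" and bool(np.any(self.counts == MISSING))

    def require_complete(self) -> None:
        if self.has_missing:
            raise ValidationError(
                f"recording {self.subject_id} contains missing bins"
            )

    def time_hours(self, midpoint: bool = True) -> np.ndarray:
        """Hours since recording start for every bin (midpoints by default)."""
        idx = np.arange(self.n_bins, dtype=float)
        if midpoint:
            idx = idx + 0.5
        return idx * self.bin_minutes / 60.0

    def daily_matrix(self) -> np.ndarray:
        """Counts reshaped to (complete days, bins per day)."""
        k = self.n_days * self.bins_per_day
        return np.asarray(self.counts[:k]).reshape(self.n_days, self.bins_per_day)


def zt_of_bin(rec: WheelRecording, bin_index: int) -> float:
    """ZT (LD) or CT (circadian frame) hour of the start of a bin, in [0, 24)."""
    minutes = bin_index * rec.bin_minutes - rec.t0_offset_minutes
    return (minutes % MINUTES_PER_DAY) / 60.0


def zt_phase_of_bin(rec: WheelRecording, bin_index: int) -> tuple[str, float]:
    """Phase label ('light'/'dark') and ZT hour of a bin of an LD recording.

    The light phase is the half-open interval ZT [0, 12); the dark phase
    ZT [12, 24).
    """
    if rec.condition != "LD":
        raise InvalidConditionError("ZT phase labels are defined only for LD recordings")
    zt = zt_of_bin(rec, bin_index)
    return ("light" if zt < 12.0 else "dark"), zt


def zt_hours_of_bins(rec: WheelRecording) -> np.ndarray:
    """Vectorised ZT/CT hour of every bin start."""
    minutes = np.arange(rec.n_bins) * rec.bin_minutes - rec.t0_offset_minutes
    return (minutes % MINUTES_PER_DAY) / 60.0


def exclude_habituation(rec: WheelRecording, n_days: int) -> WheelRecording:
    """Drop the first *n_days* complete days (habituation) and trailing
    partial days, so every remaining statistic is computed on whole days.

    The ZT/CT offset is updated so phase labels are preserved.
    """
    if n_days < 0:
        raise ValueError("n_days must be nonnegative")
    bpd = rec.bins_per_day
    drop = n_days * bpd
    if rec.n_bins < drop + bpd:
        raise InsufficientDataError(
            f"recording {rec.subject_id}: {rec.n_bins} bins < "
            f"{n_days + 1} days required"
        )
    keep_days = (rec.n_bins - drop) // bpd
    counts = rec.counts[drop : drop + keep_days * bpd]
    dropped_minutes = drop * rec.bin_minutes
    new_offset = (rec.t0_offset_minutes - dropped_minutes) % MINUTES_PER_DAY
    return replace(rec, counts=counts, t0_offset_minutes=new_offset)


def rebin(rec: WheelRecording, bin_minutes: int) -> WheelRecording:
    """Sum counts into coarser non-overlapping bins; conserves the total exactly."""
    if bin_minutes == rec.bin_minutes:
        return replace(rec)
    if bin_minutes % rec.bin_minutes != 0 or MINUTES_PER_DAY % bin_minutes != 0:
        raise ValueError(
            f"target bin {bin_minutes} min must be a multiple of "
            f"{rec.bin_minutes} min and divide 1440"
        )
    rec.require_complete()
    factor = bin_minutes // rec.bin_minutes
    k = (rec.n_bins // factor) * factor
    counts = np.asarray(rec.counts[:k]).reshape(-1, factor).sum(axis=1)
    return replace(rec, counts=counts, bin_minutes=bin_minutes)


# ---------------------------------------------------------------------------
# CSV dialect: long-format counts plus a per-subject metadata table.
# ---------------------------------------------------------------------------

_COUNT_COLUMNS = [
    "subject_id", "genotype", "sex", "age_group", "condition",
    "bin_index", "revolutions",
]
_META_COLUMNS = ["subject_id", "bin_minutes", "lights_on_clock", "t0_offset_minutes"]


def write_recordings(
    recordings: Iterable[WheelRecording], path: str | Path,
    metadata_path: str | Path | None = None,
) -> None:
    """Write recordings in the long-format CSV dialect (one row per bin)
    plus a companion per-subject metadata CSV."""
    path = Path(path)
    recordings = list(recordings)
    frames = []
    meta_rows = []
    for rec in recordings:
        frames.append(pd.DataFrame({
            "subject_id": rec.subject_id,
            "genotype": rec.genotype,
            "sex": rec.sex,
            "age_group": rec.age_group,
            "condition": rec.condition,
            "bin_index": np.arange(rec.n_bins),
            "revolutions": rec.counts,
        }))
        meta_rows.append({
            "subject_id": rec.subject_id,
            "bin_minutes": rec.bin_minutes,
            "lights_on_clock": rec.lights_on_clock or "",
            "t0_offset_minutes": rec.t0_offset_minutes,
            "frame": rec.frame,
        })
    if frames:
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    else:
        pd.DataFrame(columns=_COUNT_COLUMNS).to_csv(path, index=False)
    if metadata_path is None:
        metadata_path = path.with_name(path.stem + "_meta.csv")
    pd.DataFrame(
        meta_rows, columns=_META_COLUMNS + ["frame"] if meta_rows else _META_COLUMNS + ["frame"]
    ).to_csv(metadata_path, index=False)


def read_recordings(
    path: str | Path, metadata_path: str | Path | None = None
) -> list[WheelRecording]:
    """Read recordings from the long-format CSV dialect.

    Gaps in ``bin_index`` are filled with the explicit missing marker and a
    warning is logged; analysis operations reject recordings with missing
    bins.  Negative or fractional counts raise :class:`ValidationError`
    naming the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    for col in _COUNT_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    if metadata_path is None:
        metadata_path = path.with_name(path.stem + "_meta.csv")
    meta = None
    if Path(metadata_path).exists():
        meta = pd.read_csv(metadata_path).set_index("subject_id")

    if df.empty:
        warnings.warn(f"{path}: header-only file, no recordings", stacklevel=2)
        return []

    revs = df["revolutions"]
    frac = revs != np.floor(revs)
    if frac.any():
        row = int(np.flatnonzero(frac.to_numpy())[0])
        raise ValidationError(f"non-integer count at row {row}")
    neg = revs < 0
    if neg.any():
        row = int(np.flatnonzero(neg.to_numpy())[0])
        raise ValidationError(f"negative count at row {row}")

    out: list[WheelRecording] = []
    for sid, grp in df.groupby("subject_id", sort=False):
        grp = grp.sort_values("bin_index")
        idx = grp["bin_index"].to_numpy(dtype=np.int64)
        n = int(idx.max()) + 1
        counts = np.full(n, MISSING, dtype=np.int64)
        counts[idx] = grp["revolutions"].to_numpy(dtype=np.int64)
        if len(idx) < n:
            logger.warning(
                "subject %s: %d missing bins filled with sentinel", sid, n - len(idx)
            )
        kwargs: dict = {"bin_minutes": 1, "lights_on_clock": None,
                        "t0_offset_minutes": 0.0, "frame": "conventional"}
        if meta is not None and sid in meta.index:
            m = meta.loc[sid]
            kwargs["bin_minutes"] = int(m.get("bin_minutes", 1))
            loc = m.get("lights_on_clock", "")
            kwargs["lights_on_clock"] = None if (pd.isna(loc) or loc == "") else str(loc)
            kwargs["t0_offset_minutes"] = float(m.get("t0_offset_minutes", 0.0))
            if "frame" in m.index and not pd.isna(m["frame"]):
                kwargs["frame"] = str(m["frame"])
        out.append(WheelRecording(
            subject_id=str(sid),
            genotype=str(grp["genotype"].iloc[0]),
            sex=str(grp["sex"].iloc[0]),
            age_group=str(grp["age_group"].iloc[0]),
            condition=str(grp["condition"].iloc[0]),
            counts=counts,
            **kwargs,
        ))
    return out


# ---------------------------------------------------------------------------
# StudyTable: the long-format table every cohort-level analysis consumes.
# ---------------------------------------------------------------------------

STUDY_COLUMNS = [
    "subject_id", "genotype", "sex", "age_group", "condition",
    "outcome_measure", "value",
]


def study_table(rows: Sequence[dict] | pd.DataFrame) -> pd.DataFrame:
    """Build/validate a long-format study table: one row per
    subject x outcome measure, measures drawn from the registered vocabulary."""
    df = pd.DataFrame(rows)
    for col in STUDY_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"study table missing column {col!r}")
    bad = set(df["outcome_measure"]) - OUTCOME_MEASURES
    if bad:
        raise ValidationError(f"unregistered outcome measures: {sorted(bad)}")
    dup = df.duplicated(subset=["subject_id", "outcome_measure", "condition"])
    if dup.any():
        raise ValidationError("duplicate subject x outcome_measure rows")
    return df.reset_index(drop=True)
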