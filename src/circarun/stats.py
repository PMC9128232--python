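"""Cohort-level statistics: diurnal summaries, robust outlier screening,
the sex screen, mixed-design ANOVA with Bonferroni post hocs, and the
percentage-difference matrix.

The mixed ANOVA is the classical univariate split-plot formulation (the one
whose denominator degrees of freedom match reports like F(6, 192)), computed
in two error strata: between-subjects effects are tested against
subject-within-groups variation (an ANOVA of the per-subject means), and
within-subjects effects and their interactions with the between factors are
tested against the subject-by-within residual after subject-centering.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

from .io import MINUTES_PER_DAY, InvalidConditionError, WheelRecording, zt_hours_of_bins

__all__ = [
    "DailySummary",
    "AnovaResult",
    "diurnal_summary",
    "rout_outlier_screen",
    "sex_screen",
    "mixed_anova",
    "bonferroni_posthoc",
    "percent_difference_matrix",
]


@dataclass
class DailySummary:
    """Per-subject daily totals and active/inactive phase decomposition."""

    subject_id: str
    mean_total: float
    mean_active_phase: float
    mean_inactive_phase: float
    pct_inactive: float
    zero_activity: bool = False


@dataclass
class AnovaResult:
    """Effect table of a factorial/mixed ANOVA plus optional post hoc rows."""

    effects: pd.DataFrame  # columns: effect, F, df_num, df_den, p
    posthoc: pd.DataFrame | None = None

    def effect(self, name: str) -> pd.Series:
        rows = self.effects[self.effects["effect"] == name]
        if rows.empty:
            raise KeyError(name)
        return rows.iloc[0]


def diurnal_summary(rec: WheelRecording) -> DailySummary:
    """Mean daily total, light-phase (ZT 0-12) and dark-phase (ZT 12-24)
    wheel revolutions of an LD recording, plus the percentage of daily
    activity falling in the inactive (light) phase."""
    if rec.condition != "LD":
        raise InvalidConditionError("diurnal_summary expects an LD recording")
    rec.require_complete()
    n_days = rec.n_days
    if n_days < 1:
        raise ValueError("need at least one complete day")
    k = n_days * rec.bins_per_day
    counts = np.asarray(rec.counts[:k], dtype=float)
    zt = zt_hours_of_bins(rec)[:k]
    light = zt < 12.0
    day_idx = np.arange(k) // rec.bins_per_day
    total_by_day = np.bincount(day_idx, weights=counts, minlength=n_days)
    light_by_day = np.bincount(day_idx, weights=counts * light, minlength=n_days)
    dark_by_day = total_by_day - light_by_day
    mean_total = float(total_by_day.mean())
    mean_light = float(light_by_day.mean())
    mean_dark = float(dark_by_day.mean())
    zero = mean_total == 0
    pct = 0.0 if zero else 100.0 * mean_light / mean_total
    return DailySummary(rec.subject_id, mean_total, mean_dark, mean_light, pct, zero)


def freerun_summary(subject_id: str, alpha_rho: pd.DataFrame) -> DailySummary:
    """Daily summary of an aligned DD recording from its alpha/rho table."""
    mean_total = float(alpha_rho["total"].mean())
    mean_alpha = float(alpha_rho["alpha_counts"].mean())
    mean_rho = float(alpha_rho["rho_counts"].mean())
    zero = mean_total == 0
    pct = 0.0 if zero else 100.0 * mean_rho / mean_total
    return DailySummary(subject_id, mean_total, mean_alpha, mean_rho, pct, zero)


# ---------------------------------------------------------------------------
# ROUT outlier screen (Motulsky-Brown), constant-model variant: the screened
# quantity is a per-group sample of scalar outcome values, so the "regression"
# is the robust location fit (median) and the robust scale is the 68.27th
# percentile of absolute residuals with an N/(N-K) small-sample correction.
# Candidate outliers (at most the 30% most extreme points) are tested by an
# FDR-style step-up on t-based p-values at rate Q.
# ---------------------------------------------------------------------------

def rout_outlier_screen(
    values, q: float = 0.05, max_flagged: int | None = None
) -> np.ndarray:
    """Flag outliers in a scalar sample at false-discovery rate *q*.

    Returns a boolean mask.  Samples smaller than 5 are returned unflagged
    with a warning.  ``max_flagged`` optionally caps the number of flags
    (reported study behaviour capped at three per group; off by default).
    """
    if not (0.0 < q < 1.0):
        raise ValueError("Q must lie in (0, 1)")
    x = np.asarray(values, dtype=float)
    n = x.size
    flags = np.zeros(n, dtype=bool)
    if n < 5:
        warnings.warn(f"sample of {n} < 5 values returned unflagged", stacklevel=2)
        return flags
    resid = x - np.median(x)
    abs_r = np.abs(resid)
    k_params = 1
    rsdr = np.percentile(abs_r, 68.27) * n / (n - k_params)
    order = np.argsort(-abs_r, kind="stable")  # most extreme first
    n_cand = max(1, int(math.floor(0.3 * n)))
    if rsdr == 0:
        flags[order[:n_cand]] = abs_r[order[:n_cand]] > 0
    else:
        t = abs_r[order[:n_cand]] / rsdr
        # Effective df of the percentile-based scale: the asymptotic variance
        # of the 68.27th percentile of |Gaussian residuals| is ~0.925/n on
        # the squared-CV scale, i.e. the scale estimate carries ~0.54*n
        # observations' worth of information.  Using n-K here would overstate
        # the precision of RSDR and inflate the false-flag rate above Q.
        p = 2.0 * sps.t.sf(t, df=0.54 * n)
        cut = 0
        for i in range(n_cand):  # i-th most extreme: threshold q*(i+1)/n
            if p[i] <= q * (i + 1) / n:
                cut = i + 1
        flags[order[:cut]] = True
    if max_flagged is not None and flags.sum() > max_flagged:
        keep = order[:max_flagged]
        trimmed = np.zeros(n, dtype=bool)
        trimmed[keep] = flags[keep]
        flags = trimmed
    return flags


# ---------------------------------------------------------------------------
# ANOVA machinery
# ---------------------------------------------------------------------------

def _factorial_formula(dv: str, factors: list[str]) -> str:
    terms = "*".join(f"C({f}, Sum)" for f in factors)
    return f"{dv} ~ {terms}"


def _clean_effect_name(name: str) -> str:
    return (name.replace("C(", "").replace(", Sum)", "")
            .replace(")", "").replace(":", " x "))


def sex_screen(
    table: pd.DataFrame,
    dv: str = "value",
    factors: list[str] | None = None,
) -> AnovaResult:
    """Full-factorial ANOVA including sex, used to decide whether the cohort
    can be collapsed across sexes (no sex main effect or interaction).

    *table* is a long-format study table filtered to one outcome measure.
    """
    if factors is None:
        factors = ["sex", "genotype"]
    if "sex" not in factors:
        factors = ["sex"] + factors
    if table["sex"].nunique() < 2:
        raise ValueError("sex screen requires both sexes in the table")
    for f in factors:
        if table[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels")
    model = smf.ols(_factorial_formula(dv, factors), data=table).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    rows = []
    resid_df = float(aov.loc["Residual", "df"])
    for name, row in aov.iterrows():
        if name == "Residual":
            continue
        rows.append({
            "effect": _clean_effect_name(name),
            "F": float(row["F"]),
            "df_num": int(row["df"]),
            "df_den": resid_df,
            "p": float(row["PR(>F)"]),
        })
    return AnovaResult(effects=pd.DataFrame(rows))


def mixed_anova(
    table: pd.DataFrame,
    between: list[str],
    within: list[str],
    dv: str = "value",
    subject: str = "subject_id",
) -> AnovaResult:
    """Classical mixed-design (split-plot) ANOVA.

    Between-subjects factors are crossed with each other and with the
    crossed within-subjects factors; every subject must appear in every
    within-cell exactly once (complete design).  Results are invariant to
    row order.  A zero within-cell error with nonzero effect is reported as
    F = inf, p = 0.
    """
    df = table.copy()
    if not between or not within:
        raise ValueError("mixed_anova needs >= 1 between and >= 1 within factor")
    # completeness check
    within_cells = df.groupby(subject, sort=True)[within].apply(
        lambda g: tuple(sorted(map(tuple, g.values)))
    )
    expected = within_cells.iloc[0]
    bad = within_cells[within_cells != expected].index.tolist()
    if bad:
        raise ValueError(f"unbalanced within-subject coverage for subjects {bad}")
    k = len(expected)

    # between stratum: ANOVA of per-subject means, SS scaled by k
    keep = [subject] + between
    subj = df.groupby(keep, sort=True, as_index=False)[dv].mean()
    g_cells = subj.groupby(between, sort=True).ngroups
    model_b = smf.ols(_factorial_formula(dv, between), data=subj).fit()
    aov_b = sm.stats.anova_lm(model_b, typ=2)
    err_b_ss = float(aov_b.loc["Residual", "sum_sq"]) * k
    err_b_df = len(subj) - g_cells
    rows = []
    for name, row in aov_b.iterrows():
        if name == "Residual":
            continue
        ss = float(row["sum_sq"]) * k
        df_num = int(row["df"])
        rows.append((_clean_effect_name(name), ss, df_num, err_b_ss, err_b_df))

    # within stratum: subject-centred data against B*W factorial
    df["_centered"] = df[dv] - df.groupby(subject)[dv].transform("mean")
    model_w = smf.ols(_factorial_formula("_centered", between + within), data=df).fit()
    aov_w = sm.stats.anova_lm(model_w, typ=2)
    err_w_ss = float(model_w.ssr)
    err_w_df = (len(subj) - g_cells) * (k - 1)
    for name, row in aov_w.iterrows():
        if name == "Residual":
            continue
        eff = _clean_effect_name(name)
        involves_within = any(w in eff.split(" x ") for w in within)
        if not involves_within:
            continue  # between effects were handled in their own stratum
        rows.append((eff, float(row["sum_sq"]), int(row["df"]), err_w_ss, err_w_df))

    out = []
    for eff, ss, df_num, err_ss, err_df in rows:
        ms = ss / df_num if df_num else np.nan
        if err_df <= 0:
            f_val, p = np.nan, np.nan
        elif err_ss <= 1e-12 * max(ms, 1.0) * err_df:
            # error stratum numerically zero: infinite-F sentinel
            f_val = math.inf if ms > 0 else 0.0
            p = 0.0 if ms > 0 else 1.0
        else:
            mse = err_ss / err_df
            f_val = ms / mse
            p = float(sps.f.sf(f_val, df_num, err_df))
        out.append({"effect": eff, "F": f_val, "df_num": df_num,
                    "df_den": err_df, "p": p})
    return AnovaResult(effects=pd.DataFrame(out))


def bonferroni_posthoc(
    table: pd.DataFrame,
    contrasts: list[tuple[str, str]],
    dv: str = "value",
    group_col: str = "genotype",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise two-sample t-tests with Bonferroni adjustment.

    The family is exactly the list of requested contrasts; adjusted p is
    min(1, raw p * family size).
    """
    if not contrasts:
        raise ValueError("empty contrast family")
    levels = set(table[group_col])
    m = len(contrasts)
    rows = []
    for a, b in contrasts:
        for lvl in (a, b):
            if lvl not in levels:
                raise ValueError(f"level {lvl!r} absent from {group_col!r}")
        xa = table.loc[table[group_col] == a, dv].to_numpy(dtype=float)
        xb = table.loc[table[group_col] == b, dv].to_numpy(dtype=float)
        t, p = sps.ttest_ind(xa, xb)
        adj = min(1.0, float(p) * m)
        rows.append({
            "contrast": f"{a} vs {b}",
            "mean_diff": float(xa.mean() - xb.mean()),
            "t": float(t),
            "raw_p": float(p),
            "adjusted_p": adj,
            "significant": adj < alpha,
        })
    return pd.DataFrame(rows)


def bonferroni_adjust(raw_p: float, family_size: int) -> float:
    """min(1, raw p * family size)."""
    if family_size < 1:
        raise ValueError("family size must be >= 1")
    return min(1.0, raw_p * family_size)


def percent_difference_matrix(
    group_means: dict[tuple[str, str, str], float],
    control_map: dict[str, str],
) -> pd.DataFrame:
    """Percentage difference of each group's mean from its control group,
    per (measure, condition): 100*(group - control)/control.

    Rows are (measure, condition) pairs, columns groups; entries with a zero
    control mean are reported missing (NaN).
    """
    rows: dict[tuple[str, str], dict[str, float]] = {}
    for (group, measure, condition), value in group_means.items():
        control = control_map.get(group, group)
        ctrl_key = (control, measure, condition)
        if ctrl_key not in group_means:
            raise ValueError(f"missing control mean for {ctrl_key}")
        ctrl = group_means[ctrl_key]
        cell = np.nan if ctrl == 0 else 100.0 * (value - ctrl) / ctrl
        rows.setdefault((measure, condition), {})[group] = cell
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out.index.names = ["measure", "condition"]
    return out
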