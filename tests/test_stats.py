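import numpy as np
import pandas as pd
import pytest

from circarun.stats import (
    bonferroni_adjust,
    bonferroni_posthoc,
    diurnal_summary,
    mixed_anova,
    percent_difference_matrix,
    rout_outlier_screen,
    sex_screen,
)
from circarun.synthetic import SimulationParams, simulate_recording, square_wave_recording

from conftest import make_recording


class TestDiurnalSummary:
    def test_square_wave_all_dark_activity(self):
        rec = square_wave_recording(tau_hours=24, n_days=5, onset_hour=12,
                                    alpha_hours=12, condition="LD")
        s = diurnal_summary(rec)
        assert s.pct_inactive == 0.0
        assert s.mean_inactive_phase == 0.0

    def test_uniform_activity_splits_evenly(self):
        rec = make_recording(np.full(5 * 1440, 3), condition="LD")
        s = diurnal_summary(rec)
        assert s.pct_inactive == pytest.approx(50.0)
        assert s.mean_active_phase == s.mean_inactive_phase

    def test_pct_arithmetic(self):
        counts = np.zeros(1440, dtype=int)
        counts[:200] = 1          # 200 revolutions in the light phase
        counts[720:1120] = 2      # 800 revolutions in the dark phase
        rec = make_recording(np.tile(counts, 3), condition="LD")
        s = diurnal_summary(rec)
        assert s.mean_total == pytest.approx(1000.0)
        assert s.pct_inactive == pytest.approx(20.0)

    def test_additivity_exact_on_synthetic(self):
        rec = simulate_recording(SimulationParams(n_days=4, seed=6))
        s = diurnal_summary(rec)
        assert s.mean_active_phase + s.mean_inactive_phase == pytest.approx(
            s.mean_total, abs=1e-9)

    def test_zero_activity_flagged(self):
        rec = make_recording(np.zeros(2 * 1440, int), condition="LD")
        s = diurnal_summary(rec)
        assert s.zero_activity and s.pct_inactive == 0.0


class TestRout:
    def test_worked_sample_flags_only_gross_outlier(self):
        flags = rout_outlier_screen([1.0, 1.1, 0.9, 1.05, 0.95, 50.0], q=0.05)
        assert flags.tolist() == [False] * 5 + [True]

    def test_identical_values_unflagged(self):
        assert not rout_outlier_screen(np.full(10, 2.0)).any()

    def test_small_sample_warns_and_unflagged(self):
        with pytest.warns(UserWarning):
            flags = rout_outlier_screen([1.0, 2.0, 3.0, 100.0])
        assert not flags.any()

    def test_invalid_q_rejected(self):
        with pytest.raises(ValueError):
            rout_outlier_screen(np.arange(10.0), q=1.5)

    def test_max_flagged_cap(self):
        x = np.r_[np.random.default_rng(0).normal(0, 1, 17), 50.0, 60.0, 70.0, 80.0]
        capped = rout_outlier_screen(x, q=0.05, max_flagged=3)
        assert capped.sum() <= 3

    def test_clean_gaussian_rarely_flagged(self):
        rng = np.random.default_rng(11)
        clean = sum(
            not rout_outlier_screen(rng.normal(10, 2, 20), q=0.05).any()
            for _ in range(200)
        )
        assert clean >= 190


def _long_table(rng, n_per_cell, sex_shift=0.0, genos=("WT", "KO")):
    rows = []
    for g in genos:
        for sex in ("F", "M"):
            for i in range(n_per_cell):
                rows.append({
                    "subject_id": f"{g}{sex}{i}", "genotype": g, "sex": sex,
                    "age_group": "young", "condition": "LD",
                    "outcome_measure": "mesor",
                    "value": rng.normal(10 + (sex_shift if sex == "M" else 0), 2),
                })
    return pd.DataFrame(rows)


class TestSexScreen:
    def test_balanced_dfs_match_factorial_bookkeeping(self):
        table = _long_table(np.random.default_rng(0), 8)
        res = sex_screen(table)
        eff = {r["effect"]: r for _, r in res.effects.iterrows()}
        # 2x2 factorial, n=8/cell: each effect df 1, residual df 32-4=28
        for name in ("sex", "genotype", "sex x genotype"):
            assert eff[name]["df_num"] == 1
            assert eff[name]["df_den"] == 28

    def test_large_sex_effect_detected(self):
        table = _long_table(np.random.default_rng(1), 15, sex_shift=4.0)
        res = sex_screen(table)
        assert res.effect("sex")["p"] < 0.001

    def test_single_sex_rejected(self):
        table = _long_table(np.random.default_rng(2), 5)
        with pytest.raises(ValueError):
            sex_screen(table[table["sex"] == "F"])

    def test_null_rejection_near_alpha(self):
        rng = np.random.default_rng(3)
        rej = 0
        reps = 200
        for _ in range(reps):
            res = sex_screen(_long_table(rng, 6))
            rej += res.effect("sex")["p"] < 0.05
        assert 0.02 <= rej / reps <= 0.09


def _mixed_table(rng, n=8, geno_shift=0.0, genos=("WT", "KO")):
    rows = []
    for g in genos:
        for s in range(n):
            base = rng.normal(10 + (geno_shift if g != "WT" else 0), 2)
            for w, off in (("mesor", 0.0), ("amplitude", 3.0), ("acrophase", -1.0)):
                rows.append({
                    "subject_id": f"{g}{s}", "genotype": g,
                    "outcome_measure": w,
                    "value": base + off + rng.normal(0, 1),
                })
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        table = _mixed_table(np.random.default_rng(3), geno_shift=2.0)
        mine = mixed_anova(table, between=["genotype"], within=["outcome_measure"])
        ref = pg.mixed_anova(data=table, dv="value", within="outcome_measure",
                             subject="subject_id", between="genotype")
        ref_f = dict(zip(ref["Source"], ref["F"]))
        eff = {r["effect"]: r["F"] for _, r in mine.effects.iterrows()}
        assert eff["genotype"] == pytest.approx(ref_f["genotype"], rel=1e-9)
        assert eff["outcome_measure"] == pytest.approx(
            ref_f["outcome_measure"], rel=1e-9)
        assert eff["genotype x outcome_measure"] == pytest.approx(
            ref_f["Interaction"], rel=1e-9)

    def test_scale_invariance_of_f(self):
        table = _mixed_table(np.random.default_rng(4), geno_shift=1.0)
        a = mixed_anova(table, ["genotype"], ["outcome_measure"])
        table2 = table.assign(value=table["value"] * 10)
        b = mixed_anova(table2, ["genotype"], ["outcome_measure"])
        for ea, eb in zip(a.effects.itertuples(), b.effects.itertuples()):
            assert ea.F == pytest.approx(eb.F, rel=1e-9)
            assert ea.p == pytest.approx(eb.p, rel=1e-9)

    def test_row_order_invariance(self):
        table = _mixed_table(np.random.default_rng(5))
        a = mixed_anova(table, ["genotype"], ["outcome_measure"])
        shuffled = table.sample(frac=1, random_state=0)
        b = mixed_anova(shuffled, ["genotype"], ["outcome_measure"])
        pd.testing.assert_frame_equal(
            a.effects.sort_values("effect").reset_index(drop=True),
            b.effects.sort_values("effect").reset_index(drop=True),
        )

    def test_unbalanced_within_coverage_rejected(self):
        table = _mixed_table(np.random.default_rng(6))
        broken = table.drop(table.index[0])
        with pytest.raises(ValueError, match="subject"):
            mixed_anova(broken, ["genotype"], ["outcome_measure"])

    def test_zero_within_variance_infinite_f(self):
        rows = []
        for g, shift in (("WT", 0.0), ("KO", 5.0)):
            for s in range(4):
                for w, off in (("m1", 0.0), ("m2", 1.0)):
                    rows.append({"subject_id": f"{g}{s}", "genotype": g,
                                 "outcome_measure": w,
                                 "value": shift + off + 0.1 * s})
        res = mixed_anova(pd.DataFrame(rows), ["genotype"], ["outcome_measure"])
        eff = {r["effect"]: r for _, r in res.effects.iterrows()}
        assert eff["outcome_measure"]["F"] == np.inf
        assert eff["outcome_measure"]["p"] == 0.0

    def test_two_between_factors_df_bookkeeping(self):
        rng = np.random.default_rng(7)
        rows = []
        for g in ("WT", "KO"):
            for age in ("young", "aged"):
                for s in range(5):
                    base = rng.normal(10, 2)
                    for w in ("m1", "m2", "m3"):
                        rows.append({"subject_id": f"{g}{age}{s}", "genotype": g,
                                     "age_group": age, "outcome_measure": w,
                                     "value": base + rng.normal(0, 1)})
        res = mixed_anova(pd.DataFrame(rows), ["genotype", "age_group"],
                          ["outcome_measure"])
        eff = {r["effect"]: r for _, r in res.effects.iterrows()}
        # 20 subjects, 4 between cells, k=3 within levels
        assert eff["genotype"]["df_den"] == 16
        assert eff["genotype x outcome_measure"]["df_num"] == 2
        assert eff["genotype x outcome_measure"]["df_den"] == 32

    def test_null_genotype_rejection_near_alpha(self):
        rng = np.random.default_rng(8)
        rej = 0
        reps = 150
        for _ in range(reps):
            res = mixed_anova(_mixed_table(rng, n=8), ["genotype"],
                              ["outcome_measure"])
            rej += res.effect("genotype")["p"] < 0.05
        assert 0.015 <= rej / reps <= 0.1


class TestBonferroni:
    @pytest.mark.parametrize("raw,m,expected",
                             [(0.02, 3, 0.06), (0.6, 3, 1.0), (0.04, 1, 0.04)])
    def test_adjustment_closed_forms(self, raw, m, expected):
        assert bonferroni_adjust(raw, m) == pytest.approx(expected)

    def test_posthoc_family_size_applied(self):
        rng = np.random.default_rng(9)
        rows = [{"genotype": g, "value": rng.normal(10 + d, 1)}
                for g, d in (("A", 0), ("B", 0.5), ("C", 3))
                for _ in range(10)]
        table = pd.DataFrame(rows)
        out = bonferroni_posthoc(table, [("A", "B"), ("A", "C"), ("B", "C")])
        assert np.allclose(out["adjusted_p"],
                           np.minimum(1.0, out["raw_p"] * 3))

    def test_absent_level_rejected(self):
        table = pd.DataFrame({"genotype": ["A"] * 4, "value": [1, 2, 3, 4]})
        with pytest.raises(ValueError):
            bonferroni_posthoc(table, [("A", "Z")])

    def test_empty_family_rejected(self):
        table = pd.DataFrame({"genotype": ["A"] * 4, "value": [1, 2, 3, 4]})
        with pytest.raises(ValueError):
            bonferroni_posthoc(table, [])


class TestPercentDifference:
    def test_closed_forms(self):
        means = {("KO", "total", "LD"): 60.0, ("WT", "total", "LD"): 100.0,
                 ("TG", "total", "LD"): 170.0, ("NTG", "total", "LD"): 100.0}
        mat = percent_difference_matrix(
            means, {"KO": "WT", "TG": "NTG", "WT": "WT", "NTG": "NTG"})
        row = mat.loc[("total", "LD")]
        assert row["KO"] == pytest.approx(-40.0)
        assert row["TG"] == pytest.approx(70.0)
        assert row["WT"] == 0.0

    def test_zero_control_reported_missing(self):
        means = {("KO", "m", "LD"): 5.0, ("WT", "m", "LD"): 0.0}
        mat = percent_difference_matrix(means, {"KO": "WT", "WT": "WT"})
        assert np.isnan(mat.loc[("m", "LD"), "KO"])

    def test_missing_control_mean_rejected(self):
        with pytest.raises(ValueError):
            percent_difference_matrix({("KO", "m", "LD"): 5.0}, {"KO": "WT"})
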