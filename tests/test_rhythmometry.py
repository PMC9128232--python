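import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circarun.io import ValidationError
from circarun.periodometry import harmonic_regression
from circarun.rhythmometry import (
    cosinor_fit,
    rhythm_parameters_table,
    runs_test,
)

from conftest import cosine_series, make_recording


def brute_force_cosinor(y, bin_minutes, tau, m_grid, a_grid, phi_grid):
    """Independent oracle: grid search over (M, A, phi) minimizing SSE.

    Uses the algebraic expansion of sum((y - M - A*c(phi))^2) so the full
    grid is evaluated exactly without looping over data points.
    """
    t = (np.arange(y.size) + 0.5) * bin_minutes / 60.0
    w = 2 * np.pi / tau
    n = y.size
    syy = float(y @ y)
    sy = float(y.sum())
    best = (np.inf, None)
    M = m_grid[:, None]
    A = a_grid[None, :]
    for phi in phi_grid:
        c = np.cos(w * (t - phi))
        sc = c.sum()
        scc = float(c @ c)
        syc = float(y @ c)
        sse = (syy - 2 * M * sy - 2 * A * syc + n * M**2
               + 2 * M * A * sc + A**2 * scc)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        if sse[i, j] < best[0]:
            best = (sse[i, j], (m_grid[i], a_grid[j], phi))
    return best[1]


def enumerate_runs_p(signs):
    """Independent oracle: exact two-sided runs-test p by enumerating every
    arrangement of the observed sign counts."""
    signs = np.asarray(signs)
    n = signs.size
    n_pos = int((signs > 0).sum())
    obs_runs = 1 + int((signs[1:] != signs[:-1]).sum())
    counts = {}
    for pos in itertools.combinations(range(n), n_pos):
        seq = np.full(n, -1)
        seq[list(pos)] = 1
        r = 1 + int((seq[1:] != seq[:-1]).sum())
        counts[r] = counts.get(r, 0) + 1
    total = math.comb(n, n_pos)
    lower = sum(v for r, v in counts.items() if r <= obs_runs) / total
    upper = sum(v for r, v in counts.items() if r >= obs_runs) / total
    return min(1.0, 2 * min(lower, upper))


class TestCosinorFit:
    def test_exact_recovery(self):
        y = cosine_series(20, 15, 18, 24, 7)
        fit = cosinor_fit(y, 24.0)
        assert fit.mesor == pytest.approx(20.0, abs=1e-9)
        assert fit.amplitude == pytest.approx(15.0, abs=1e-9)
        assert fit.acrophase_hours == pytest.approx(18.0, abs=1e-9)

    def test_white_noise_mesor_within_se_and_ns_amplitude(self):
        hits = 0
        ns = 0
        reps = 200
        for seed in range(reps):
            y = np.random.default_rng(seed).normal(10, 2, 7 * 1440)
            fit = cosinor_fit(y, 24.0)
            hits += abs(fit.mesor - 10) < 3 * fit.se_mesor
            ns += fit.p_value >= 0.05
        assert hits >= 0.95 * reps
        assert ns >= 0.90 * reps  # zero-amplitude test non-significant

    def test_matches_brute_force_grid(self):
        # 2-day toy series, coarse bins; oracle grid at the same resolution
        y = cosine_series(10, 6, 7, 24, 2, bin_minutes=10, noise_sd=1.0, seed=3)
        fit = cosinor_fit(y, 24.0, bin_minutes=10)
        m_grid = np.arange(9.0, 11.0 + 1e-9, 0.01)
        a_grid = np.arange(5.0, 7.0 + 1e-9, 0.01)
        phi_grid = np.arange(0.0, 24.0, 0.01)
        m, a, phi = brute_force_cosinor(y, 10, 24.0, m_grid, a_grid, phi_grid)
        assert fit.mesor == pytest.approx(m, abs=0.011)
        assert fit.amplitude == pytest.approx(a, abs=0.011)
        assert fit.acrophase_hours == pytest.approx(phi, abs=0.011)

    def test_acrophase_equivariance_under_circular_shift(self):
        y = cosine_series(20, 15, 6, 24, 6)
        base = cosinor_fit(y, 24.0)
        shifted = cosinor_fit(np.roll(y, 180), 24.0)  # +3 h shift
        assert shifted.mesor == pytest.approx(base.mesor, abs=1e-8)
        assert shifted.amplitude == pytest.approx(base.amplitude, abs=1e-8)
        dphi = (shifted.acrophase_hours - base.acrophase_hours) % 24.0
        assert dphi == pytest.approx(3.0, abs=1e-6)

    def test_scaling_counts_scales_mesor_amplitude_only(self):
        y = cosine_series(20, 15, 6, 24, 4, noise_sd=3.0, seed=1)
        a = cosinor_fit(y, 24.0)
        b = cosinor_fit(2.5 * y, 24.0)
        assert b.mesor == pytest.approx(2.5 * a.mesor, rel=1e-9)
        assert b.amplitude == pytest.approx(2.5 * a.amplitude, rel=1e-9)
        assert b.acrophase_hours == pytest.approx(a.acrophase_hours, abs=1e-9)

    def test_amplitude_identical_to_harmonic_regression(self):
        rng = np.random.default_rng(7)
        rec = make_recording(rng.poisson(15, 4 * 1440), condition="DD")
        c = cosinor_fit(rec, 24.37)
        h = harmonic_regression(rec, 24.37)
        assert c.amplitude == pytest.approx(h.amplitude, rel=1e-12)
        assert c.mesor == pytest.approx(h.intercept, rel=1e-12)

    def test_fitted_curve_mean_equals_mesor_over_whole_cycles(self):
        y = cosine_series(20, 15, 18, 24, 7, noise_sd=2.0, seed=2)
        fit = cosinor_fit(y, 24.0)
        t = (np.arange(y.size) + 0.5) / 60.0
        curve = fit.mesor + fit.amplitude * np.cos(
            2 * np.pi * (t - fit.acrophase_hours) / 24.0)
        assert curve.mean() == pytest.approx(fit.mesor, abs=1e-9)


class TestRunsTest:
    def test_alternating_signs_most_extreme_high(self):
        signs = np.tile([1.0, -1.0], 6)
        n_runs, p = runs_test(signs)
        assert n_runs == 12
        assert p == pytest.approx(enumerate_runs_p(np.sign(signs)), abs=1e-12)

    def test_all_positive_boundary(self):
        n_runs, p = runs_test(np.ones(10))
        assert n_runs == 1
        assert p == pytest.approx(2.0 ** (1 - 10))

    def test_zeros_dropped(self):
        n_runs, _ = runs_test([1.0, 0.0, 1.0, -1.0, 0.0, -1.0])
        assert n_runs == 2

    @pytest.mark.parametrize("n", range(2, 13))
    def test_exact_p_matches_enumeration_all_lengths(self, n):
        rng = np.random.default_rng(n)
        for _ in range(20):
            signs = rng.choice([-1.0, 1.0], size=n)
            if len(set(signs)) < 2:
                continue
            _, p = runs_test(signs)
            assert p == pytest.approx(enumerate_runs_p(signs), abs=1e-12)

    def test_null_calibration(self):
        rng = np.random.default_rng(0)
        rej = 0
        reps = 600
        for _ in range(reps):
            _, p = runs_test(rng.normal(size=100))
            rej += p < 0.05
        assert 0.025 <= rej / reps <= 0.075

    @given(st.integers(0, 5000))
    @settings(max_examples=30, deadline=None)
    def test_p_always_valid(self, seed):
        rng = np.random.default_rng(seed)
        _, p = runs_test(rng.normal(size=rng.integers(2, 60)))
        assert 0.0 <= p <= 1.0


class TestParametersTable:
    def _fits(self, n):
        out = []
        for i in range(n):
            y = cosine_series(20, 15, 18, 24, 2, noise_sd=2.0, seed=i)
            fit = cosinor_fit(y, 24.0)
            fit.subject_id = f"m{i}"
            out.append(fit)
        return out

    def _meta(self, n):
        return pd.DataFrame([{
            "subject_id": f"m{i}", "genotype": "WT", "sex": "F",
            "age_group": "young", "condition": "LD"} for i in range(n)])

    def test_three_rows_per_subject(self):
        table = rhythm_parameters_table(self._fits(3), self._meta(3))
        assert len(table) == 9
        assert set(table["outcome_measure"]) == {"mesor", "amplitude", "acrophase"}

    def test_poor_fit_flagged_not_dropped(self):
        fits = self._fits(1)
        fits[0].runs_p = 0.001
        table = rhythm_parameters_table(fits, self._meta(1))
        assert table["poor_fit"].all()
        assert len(table) == 3

    def test_duplicate_subject_rejected(self):
        fits = self._fits(2)
        fits[1].subject_id = fits[0].subject_id
        with pytest.raises(ValidationError):
            rhythm_parameters_table(fits, self._meta(2))

    def test_empty_input_gives_empty_table(self):
        table = rhythm_parameters_table([], self._meta(0))
        assert table.empty
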