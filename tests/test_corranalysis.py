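"""Row alignment, through-origin regression, rate normalization, f_surf."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kymocorr import (
    align_rows_by_xcorr,
    fit_slope_through_origin,
    incorporation_analysis,
    normalized_incorporation,
    simulate_cell_movie,
    surface_fraction,
)
from kymocorr.corranalysis import _group_slopes

from conftest import noise_free, small_config


def brute_force_slope(x, y, lo=-10.0, hi=10.0, rounds=6, n=1001):
    """Independent oracle: iterative grid minimization of sum((y - s*x)**2)."""
    for _ in range(rounds):
        grid = np.linspace(lo, hi, n)
        sse = ((y[None, :] - grid[:, None] * x[None, :]) ** 2).sum(axis=1)
        i = int(np.argmin(sse))
        lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, n - 1)]
    return 0.5 * (lo + hi)


class TestThroughOriginFit:
    def test_exact_line_through_origin(self):
        slope, r2, _ = fit_slope_through_origin([1, 2, 3], [2, 4, 6])
        assert slope == pytest.approx(2.0)
        assert r2 == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # least squares through the origin: slope = sum(xy)/sum(x^2) = 23/14
        slope, _, _ = fit_slope_through_origin([1, 2, 3], [2, 3, 5])
        assert slope == pytest.approx(23 / 14, abs=1e-12)

    def test_independent_noise_gives_negligible_r_squared(self, rng):
        x = rng.uniform(1, 2, size=10_000)
        y = rng.uniform(1, 2, size=10_000)
        _, r2, _ = fit_slope_through_origin(x, y)
        assert r2 < 0.01

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 30)
        x = rng.normal(1.0, 1.0, n)
        while np.allclose(x, 0):
            x = rng.normal(1.0, 1.0, n)
        y = rng.normal(0.0, 2.0, n)
        slope, _, _ = fit_slope_through_origin(x, y)
        assert slope == pytest.approx(brute_force_slope(x, y), abs=1e-6)

    def test_all_zero_x_rejected(self):
        with pytest.raises(ValueError):
            fit_slope_through_origin([0, 0, 0], [1, 2, 3])


class TestRowAlignment:
    def test_identical_kymographs_zero_lags(self, rng):
        K = rng.normal(100, 10, size=(8, 50))
        x, y, lags, flagged = align_rows_by_xcorr(K, K, max_lag_frames=5)
        assert (lags == 0).all()
        np.testing.assert_array_equal(x, y)

    def test_constructed_shift_recovered(self, rng):
        T, shift = 60, 3
        base = rng.normal(100, 10, size=(6, T + shift))
        ref = base[:, shift:]
        probe = base[:, :T]  # probe trails reference by `shift` frames
        _, _, lags, _ = align_rows_by_xcorr(probe, ref, max_lag_frames=8)
        assert (lags == shift).all()

    def test_max_lag_zero_returns_raw_pairs(self, rng):
        P = rng.normal(size=(4, 20))
        R = rng.normal(size=(4, 20))
        x, y, lags, _ = align_rows_by_xcorr(P, R, max_lag_frames=0)
        assert x.size == y.size == 80
        np.testing.assert_array_equal(x, R.ravel())
        np.testing.assert_array_equal(y, P.ravel())

    def test_constant_row_flagged_with_zero_lag(self, rng):
        P = np.full((3, 30), 5.0)
        R = rng.normal(size=(3, 30))
        _, _, lags, flagged = align_rows_by_xcorr(P, R, max_lag_frames=4)
        assert set(flagged) == {0, 1, 2}
        assert (lags == 0).all()


class TestNormalization:
    @pytest.mark.parametrize(
        "s, b, a, expected_r, expected_pct",
        [
            (0.69, 0.10, 0.94, 0.7024, 70),  # wildtype 30-residue linker probe
            (0.70, 0.10, 0.94, 0.7143, 71),
            (0.09, 0.10, 0.94, 0.0, 0),  # below baseline: floored
            (0.94, 0.10, 0.94, 1.0, 100),  # the standard itself
            (0.10, 0.10, 0.94, 0.0, 0),  # the baseline itself
        ],
    )
    def test_table_style_reporting(self, s, b, a, expected_r, expected_pct):
        r, pct = normalized_incorporation(s, b, a)
        assert r == pytest.approx(expected_r, abs=1e-4)
        assert pct == expected_pct

    def test_degenerate_normalization_rejected(self):
        with pytest.raises(ValueError):
            normalized_incorporation(0.5, 0.9, 0.9)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.floats(-2, 2), st.floats(0, 0.5), st.floats(0.6, 2),
    )
    def test_rate_always_in_unit_interval(self, s, b, a):
        r, pct = normalized_incorporation(s, b, a)
        assert 0.0 <= r <= 1.0
        assert 0 <= pct <= 100


class TestSurfaceFraction:
    def test_headline_value(self):
        # wildtype 0.70 vs proline-binding-deficient 0.17 -> ~75% from surface
        assert surface_fraction(0.70, 0.17) == pytest.approx(0.757, abs=1e-3)

    def test_equal_rates_no_surface_contribution(self):
        assert surface_fraction(0.5, 0.5) == 0.0

    def test_zero_solution_rate_all_surface(self):
        assert surface_fraction(0.5, 0.0) == 1.0

    def test_model_violation_rejected(self):
        with pytest.raises(ValueError):
            surface_fraction(0.3, 0.5)


class TestCohortPipeline:
    def test_probe_equals_standard_gives_unity(self):
        movies = [simulate_cell_movie(small_config(rho=1.0, rng_seed=s))[0]
                  for s in (1, 2)]
        base = [simulate_cell_movie(small_config(rho=0.0, rng_seed=s))[0]
                for s in (3, 4)]
        res = incorporation_analysis(movies, base, movies)
        assert res.r == pytest.approx(1.0)
        assert res.percent == 100

    def test_probe_equals_baseline_gives_zero(self):
        std = [simulate_cell_movie(small_config(rho=1.0, rng_seed=s))[0]
               for s in (1, 2)]
        base = [simulate_cell_movie(small_config(rho=0.0, rng_seed=s))[0]
                for s in (3, 4)]
        res = incorporation_analysis(base, base, std)
        assert res.r == pytest.approx(0.0)

    def test_empty_group_error_names_group(self):
        movie = simulate_cell_movie(small_config())[0]
        with pytest.raises(ValueError, match="baseline"):
            incorporation_analysis([movie], [], [movie])

    def test_slope_monotonic_in_rho_noise_free(self):
        slopes = []
        for rho in (0.0, 0.25, 0.5, 0.75, 1.0):
            movie, _ = simulate_cell_movie(noise_free(rho=rho))
            slopes.append(_group_slopes([movie], "g")[0][0])
        assert np.all(np.diff(slopes) > 0)

    def test_rate_invariant_to_global_channel_scaling(self):
        # multiplying the probe channel of every movie by a constant leaves r
        # unchanged: preprocessing mean-matching absorbs the scale
        def cohort(rho, seeds, gain=1.0):
            out = []
            for s in seeds:
                m, _ = simulate_cell_movie(small_config(rho=rho, rng_seed=s))
                arr = m.intensities.copy()
                arr[:, 1] *= gain
                out.append(m.with_intensities(arr))
            return out

        probe_a = cohort(0.6, (1, 2))
        base_a = cohort(0.0, (3, 4))
        std_a = cohort(1.0, (5, 6))
        r1 = incorporation_analysis(probe_a, base_a, std_a).r
        r2 = incorporation_analysis(
            cohort(0.6, (1, 2), gain=3.0),
            cohort(0.0, (3, 4), gain=3.0),
            cohort(1.0, (5, 6), gain=3.0),
        ).r
        assert r2 == pytest.approx(r1, abs=1e-6)
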