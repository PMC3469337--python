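import numpy as np
import pytest

from pegconf import (
    BinodalDataset,
    PolarityDataset,
    et30_calibration,
    et30_slope,
    fit_scaling,
    linear_fit,
    min_peg_for_phase,
    relative_molar_fraction,
)


class TestScalingFit:
    def test_noise_free_power_law_recovered_exactly(self):
        mw = np.array([300.0, 500, 900, 1500, 2500, 3500])
        pts = np.column_stack([mw, 0.3 * mw**0.5])
        for method in ("lar", "ols"):
            fit = fit_scaling(pts, method=method, seed=0)
            assert fit.exponent_v == pytest.approx(0.5, abs=1e-9)
            assert fit.prefactor == pytest.approx(0.3, rel=1e-9)
            lo, hi = fit.ci95
            assert hi - lo < 1e-8  # degenerate CI on exact data

    def test_lar_equals_ols_without_noise(self):
        mw = np.geomspace(300, 3500, 8)
        pts = np.column_stack([mw, 0.2 * mw**0.55])
        lar = fit_scaling(pts, method="lar", seed=1)
        ols = fit_scaling(pts, method="ols", seed=1)
        assert lar.exponent_v == pytest.approx(ols.exponent_v, abs=1e-9)

    def test_noisy_exponent_recovery_within_ci(self):
        """5% lognormal noise, n=7: the CI covers the true exponent in at
        least 90% of replicates."""
        rng = np.random.default_rng(2024)
        mw = np.geomspace(300, 3500, 7)
        hits = 0
        n_rep = 40
        for _ in range(n_rep):
            rg = 0.25 * mw**0.6 * np.exp(rng.normal(0, 0.05, size=7))
            fit = fit_scaling(np.column_stack([mw, rg]), seed=int(rng.integers(2**31)))
            lo, hi = fit.ci95
            hits += lo <= 0.6 <= hi
        assert hits >= 0.9 * n_rep

    def test_lar_resists_a_gross_outlier(self):
        mw = np.geomspace(300, 3500, 10)
        rg = 0.3 * mw**0.5
        rg[4] *= 5.0  # gross outlier
        pts = np.column_stack([mw, rg])
        err_lar = abs(fit_scaling(pts, method="lar", seed=3).exponent_v - 0.5)
        err_ols = abs(fit_scaling(pts, method="ols", seed=3).exponent_v - 0.5)
        assert err_lar < 0.25 * err_ols

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_scaling([(300.0, 5.0), (400.0, 6.0)])
        with pytest.raises(ValueError):
            fit_scaling([(300.0, 5.0), (400.0, -6.0), (500.0, 7.0)])
        with pytest.raises(ValueError):
            fit_scaling([(300.0, 5.0), (400.0, 6.0), (500.0, 7.0)], method="huber")


class TestLinearFit:
    def test_exact_line(self):
        x = np.arange(5.0)
        fit = linear_fit(x, 2.0 * x + 1.0)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_anticorrelated_line_keeps_r2_of_one(self):
        x = np.arange(6.0)
        fit = linear_fit(x, -3.0 * x + 4.0)
        assert fit.slope == pytest.approx(-3.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_null_r_squared_distribution(self):
        """For independent x, y the mean R² over replicates is 1/(n-1)."""
        rng = np.random.default_rng(9)
        n = 100
        r2 = [
            linear_fit(rng.normal(size=n), rng.normal(size=n)).r_squared
            for _ in range(300)
        ]
        assert np.mean(r2) == pytest.approx(1.0 / (n - 1), abs=0.004)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            linear_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBinodalInterpolation:
    def test_midpoint_of_linear_segment(self):
        binodal = BinodalDataset({600.0: [(10.0, 20.0), (20.0, 10.0)]})
        assert min_peg_for_phase(binodal, 600.0, 15.0) == pytest.approx(15.0)

    def test_knot_returns_exactly(self):
        binodal = BinodalDataset({600.0: [(5.0, 30.0), (10.0, 18.0), (20.0, 9.0)]})
        assert min_peg_for_phase(binodal, 600.0, 10.0) == 18.0

    def test_interpolation_bracketed_by_knots(self):
        rng = np.random.default_rng(4)
        po4 = np.linspace(2.0, 25.0, 20)
        peg = 50.0 * np.exp(-po4 / 8.0)  # convex, monotone decreasing
        binodal = BinodalDataset({1000.0: np.column_stack([po4, peg])})
        for q in rng.uniform(2.0, 25.0, size=25):
            lo = peg[po4 >= q].max() if np.any(po4 >= q) else peg[-1]
            hi = peg[po4 <= q].max()
            val = min_peg_for_phase(binodal, 1000.0, q)
            left = np.searchsorted(po4, q) - 1
            assert min(peg[left], peg[left + 1]) <= val <= max(peg[left], peg[left + 1])

    def test_extrapolation_refused(self):
        binodal = BinodalDataset({600.0: [(10.0, 20.0), (20.0, 10.0)]})
        with pytest.raises(ValueError, match="extrapolate"):
            min_peg_for_phase(binodal, 600.0, 25.0)

    def test_csv_round_trip(self, tmp_path):
        import pandas as pd

        path = tmp_path / "binodal.csv"
        pd.DataFrame(
            {"peg_mw": [600.0, 600.0, 1000.0, 1000.0],
             "po4_pct": [10.0, 20.0, 8.0, 18.0],
             "peg_pct": [20.0, 10.0, 16.0, 7.0]}
        ).to_csv(path, index=False)
        binodal = BinodalDataset.from_csv(path)
        assert set(binodal.curves) == {600.0, 1000.0}
        assert min_peg_for_phase(binodal, 1000.0, 13.0) == pytest.approx(11.5)

    def test_missing_file_and_columns(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            BinodalDataset.from_csv(tmp_path / "nope.csv")
        bad = tmp_path / "bad.csv"
        bad.write_text("a,b\n1,2\n")
        with pytest.raises(ValueError, match="missing required columns"):
            BinodalDataset.from_csv(bad)


class TestRelativeMolarFraction:
    def test_scaling_factors(self):
        ds = PolarityDataset(
            {
                200.0: [(0.10, 60.0), (0.20, 58.0)],
                400.0: [(0.10, 59.0), (0.15, 57.0)],
                1450.0: [(0.01, 61.0), (0.02, 60.0)],
            }
        )
        out = relative_molar_fraction(ds)
        np.testing.assert_allclose(out[200.0][:, 0], [0.10, 0.20])  # factor 1
        np.testing.assert_allclose(out[400.0][:, 0], [0.20, 0.30])  # factor 2
        np.testing.assert_allclose(out[1450.0][:, 0], [0.07, 0.14])  # round(7.25) = 7

    def test_et30_values_untouched(self):
        ds = PolarityDataset({600.0: [(0.05, 59.5), (0.10, 58.0)]})
        out = relative_molar_fraction(ds)
        np.testing.assert_allclose(out[600.0][:, 1], [59.5, 58.0])


class TestET30Slope:
    def test_fully_linear_series_uses_all_points(self):
        x = np.linspace(0.0, 0.4, 8)
        fit = et30_slope(np.column_stack([x, 63.0 - 10.0 * x]))
        assert fit.slope == pytest.approx(-10.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_linear_prefix_recovered_despite_curvature(self):
        x = np.linspace(0.0, 0.5, 12)
        y = 63.0 - 8.0 * x
        curved = x > 0.25
        y[curved] -= 2000.0 * (x[curved] - 0.25) ** 2  # sharp downward curvature
        fit = et30_slope(np.column_stack([x, y]))
        assert fit.slope == pytest.approx(-8.0, rel=0.05)

    def test_decreasing_polarity_gives_negative_slope(self):
        x = np.linspace(0.0, 0.3, 6)
        fit = et30_slope(np.column_stack([x, 63.0 - 12.0 * x]))
        assert fit.slope < 0

    def test_no_linear_region_is_an_error(self):
        rng = np.random.default_rng(13)
        x = np.linspace(0.0, 1.0, 10)
        y = rng.normal(size=10) * 10
        with pytest.raises(ValueError, match="linear region"):
            et30_slope(np.column_stack([x, y]))


class TestET30Calibration:
    def test_three_points_interpolated_exactly(self):
        pts = [(520.0, 52.0), (560.0, 49.0), (600.0, 45.0)]
        cal = et30_calibration(pts)
        for wl, et in pts:
            assert cal(wl) == pytest.approx(et, abs=1e-9)

    def test_known_quadratic_recovered_under_small_noise(self):
        rng = np.random.default_rng(17)
        true = np.array([0.002, -2.5, 800.0])
        wl = np.linspace(500, 650, 12)
        et = np.polyval(true, wl) + rng.normal(0, 0.05, size=12)
        cal = et30_calibration(np.column_stack([wl, et]))
        _, cov = np.polyfit(wl, et, 2, cov=True)
        se = np.sqrt(np.diag(cov))
        np.testing.assert_array_less(np.abs(cal.coefficients - true), 3 * se + 1e-12)

    def test_insufficient_points_rejected(self):
        with pytest.raises(ValueError):
            et30_calibration([(520.0, 52.0), (560.0, 49.0)])
        with pytest.raises(ValueError):
            et30_calibration([(520.0, 52.0), (520.0, 49.0), (520.0, 45.0)])
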