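import numpy as np
import pytest

from sporoquant import (
    CalibrationModel,
    coverage_fraction,
    density_from_count,
    expand_band,
    fit_linear,
    predict_band,
    prediction_interval,
    with_expanded_errors,
)
from sporoquant.synthetic import CalibrationSetParams, generate_calibration_set
from .oracles import ols_three_point


class TestDensityFromCount:
    def test_zero(self):
        assert density_from_count(0, 0.0625) == 0.0

    def test_grid_cell_conversion(self):
        # 125 conidia on a 2.5 x 2.5 mm cell = 0.0625 cm²
        assert density_from_count(125, 0.0625) == pytest.approx(2000.0)

    def test_crop_conversion_reaches_working_range_floor(self):
        # 50 conidia on a 500 x 500 µm² crop = 0.0025 cm² -> 2.0e4 cm⁻²
        assert density_from_count(50, 0.0025) == pytest.approx(0.2e5)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            density_from_count(5, 0.0)


class TestFitLinear:
    def test_noiseless_line_recovered_exactly(self):
        g = np.linspace(40, 180, 12)
        pts = list(zip(g, 1250 * g - 100))
        m = fit_linear(pts)
        assert m.slope == pytest.approx(1250.0)
        assert m.intercept == pytest.approx(-100.0)
        assert m.r_squared == pytest.approx(1.0)
        assert m.slope_err == pytest.approx(0.0, abs=1e-4)

    def test_three_point_closed_form(self):
        pts = [(0.0, 0.0), (1.0, 2.0), (2.0, 2.0)]
        m = fit_linear(pts)
        slope, intercept, r2 = ols_three_point(pts)
        assert (slope, intercept, r2) == pytest.approx((1.0, 1 / 3, 0.75))
        assert m.slope == pytest.approx(slope)
        assert m.intercept == pytest.approx(intercept)
        assert m.r_squared == pytest.approx(r2)

    def test_random_sets_match_closed_form(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            pts = list(zip(rng.uniform(0, 200, 8), rng.normal(0, 1000, 8)))
            m = fit_linear(pts)
            slope, intercept, r2 = ols_three_point(pts)
            assert m.slope == pytest.approx(slope)
            assert m.intercept == pytest.approx(intercept)
            assert m.r_squared == pytest.approx(r2)

    def test_degenerate_gray_rejected(self):
        with pytest.raises(ValueError):
            fit_linear([(5.0, 1.0), (5.0, 2.0), (5.0, 3.0)])
        with pytest.raises(ValueError):
            fit_linear([(1.0, 2.0), (2.0, 3.0)])


class TestPredictBand:
    eq1 = CalibrationModel(slope=1250, intercept=-100, slope_err=60,
                           intercept_err=3650, n_points=25)
    eq2 = CalibrationModel(slope=1250, intercept=-100, band_mode="expanded",
                           slope_err_expanded=250, intercept_err_expanded=8000,
                           n_points=25)

    def test_fit_band_at_g100(self):
        b = predict_band(self.eq1, 100)
        assert b.central == pytest.approx(124900)
        assert (b.lower, b.upper) == pytest.approx((115250, 134550))

    def test_expanded_band_at_g100_uses_slope_only_center(self):
        b = predict_band(self.eq2, 100)
        assert b.central == pytest.approx(125000)
        assert (b.lower, b.upper) == pytest.approx((92000, 158000))

    def test_intercept_only_at_g0(self):
        b = predict_band(self.eq1, 0)
        assert b.central == pytest.approx(-100)
        assert b.upper == pytest.approx(3550)
        assert b.floored and b.lower == 0.0

    def test_out_of_range_gray_rejected(self):
        with pytest.raises(ValueError):
            predict_band(self.eq1, 300)

    def test_prediction_interval_alternative(self):
        rng = np.random.default_rng(2)
        g = rng.uniform(50, 175, 30)
        c = 1250 * g - 100 + rng.normal(0, 15000, 30)
        m = fit_linear(list(zip(g, c)))
        b = prediction_interval(m, 100.0, level=0.95)
        assert b.lower < b.central < b.upper
        # 95% interval should be roughly ±2 residual sd
        assert b.upper - b.lower == pytest.approx(4 * m.residual_sd, rel=0.2)


class TestCoverage:
    def test_points_on_central_line_covered(self):
        m = TestPredictBand.eq1
        pts = [(g, 1250 * g - 100) for g in (50, 100, 150)]
        assert coverage_fraction(m, pts) == 1.0

    def test_zero_errors_cover_only_exact_hits(self):
        m = CalibrationModel(slope=1250, intercept=-100, n_points=25)
        rng = np.random.default_rng(1)
        pts = [(g, 1250 * g - 100 + rng.normal(0, 5000)) for g in range(50, 170, 5)]
        assert coverage_fraction(m, pts) == 0.0

    def test_empty_points_rejected(self):
        with pytest.raises(ValueError):
            coverage_fraction(TestPredictBand.eq1, [])


class TestExpandBand:
    @staticmethod
    def fitted_with_noise(seed=3):
        pts = generate_calibration_set(CalibrationSetParams(seed=seed))
        return fit_linear(pts), pts

    def test_already_covered_keeps_k_one(self):
        m = CalibrationModel(slope=1250, intercept=-100, slope_err=60,
                             intercept_err=3650, n_points=10)
        pts = [(g, 1250 * g - 100) for g in np.linspace(50, 175, 10)]
        expanded = expand_band(m, pts, target_coverage=1.0)
        assert expanded.expansion_factor == 1.0

    @pytest.mark.parametrize("q", [0.5, 0.8, 0.95, 1.0])
    def test_postcondition_coverage_reached(self, q):
        m, pts = self.fitted_with_noise()
        expanded = expand_band(m, pts, q)
        assert coverage_fraction(expanded, pts) >= q
        assert expanded.band_mode == "expanded"

    def test_k_monotone_in_target_and_minimal(self):
        m, pts = self.fitted_with_noise(seed=9)
        ks = [expand_band(m, pts, q).expansion_factor for q in (0.4, 0.6, 0.8, 0.95, 1.0)]
        assert ks == sorted(ks)
        # minimality against a brute-force scan of k
        q = 0.8
        k_star = expand_band(m, pts, q).expansion_factor
        grid = np.arange(1.0, k_star + 1.0, 0.01)
        feasible = [
            k for k in grid
            if coverage_fraction(with_expanded_errors(m, k * m.slope_err, k * m.intercept_err), pts) >= q
        ]
        assert feasible and abs(min(feasible) - k_star) <= 0.02

    def test_band_nesting(self):
        m, pts = self.fitted_with_noise(seed=5)
        expanded = expand_band(m, pts, 0.95)
        for g in (50, 100, 175):
            fit_b = predict_band(m, g)
            exp_b = predict_band(expanded, g)
            assert exp_b.upper - exp_b.lower >= fit_b.upper - fit_b.lower

    def test_unreachable_target_errors(self):
        m = CalibrationModel(slope=1.0, intercept=0.0, slope_err=0.0,
                             intercept_err=0.0, n_points=3)
        with pytest.raises(ValueError):
            expand_band(m, [(10.0, 999.0)], 1.0)


class TestSerialization:
    def test_json_roundtrip(self, tmp_path):
        m, _ = TestExpandBand.fitted_with_noise()
        path = tmp_path / "model.json"
        m.to_json(path)
        back = CalibrationModel.from_json(path)
        assert back == m

    def test_validation(self):
        with pytest.raises(ValueError):
            CalibrationModel(slope=1, intercept=0, r_squared=1.5, n_points=5)
        with pytest.raises(ValueError):
            CalibrationModel(slope=1, intercept=0, band_mode="expanded", n_points=5)
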