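"""Model fitting: constrained mechanistic, empirical polynomial, logistic,
linear calibration, and the correlation screen."""

import numpy as np
import pytest
from scipy import stats

from recombrisk.fitting import (
    FitError,
    InsufficientDataError,
    ModelKind,
    correlation_screen,
    fit_h_mechanistic,
    fit_linear,
    fit_logistic,
    fit_polynomial,
    smoothed_sem_weights,
)
from recombrisk.models import (
    DEFAULT_G_PARAMS,
    DEFAULT_H_PARAMS,
    g_of_err,
    h_of_err,
)

PANEL_ERRS = np.array([0.0, 0.4, 1.0, 1.4, 2.4, 3.2, 3.6, 7.0, 9.0])


class TestMechanisticHFit:
    def test_exact_recovery_on_noiseless_panel(self):
        pts = [(e, h_of_err(e)) for e in PANEL_ERRS]
        res = fit_h_mechanistic(pts)
        assert res.params.k1 == pytest.approx(0.9, abs=1e-6)
        assert res.params.err_max == pytest.approx(10.28, abs=1e-5)
        assert np.max(np.abs(res.residuals)) < 1e-8
        assert res.r == pytest.approx(1.0, abs=1e-9)

    def test_k0_reported_as_derived(self):
        pts = [(e, h_of_err(e)) for e in PANEL_ERRS]
        p = fit_h_mechanistic(pts).params
        assert p.k0 == pytest.approx(p.k1 * p.err_max**2 / 4, rel=1e-12)

    def test_zero_signal_flags_boundary(self):
        res = fit_h_mechanistic([(e, 0.0) for e in PANEL_ERRS])
        assert res.params.k1 == pytest.approx(0.0, abs=1e-6)
        assert any("zero-signal" in f for f in res.flags)

    def test_insufficient_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_h_mechanistic([(0, 0), (1, 1)])

    def test_weighted_equals_unweighted_for_equal_weights(self):
        pts = [(e, h_of_err(e) + (-1.0) ** i) for i, e in enumerate(PANEL_ERRS)]
        a = fit_h_mechanistic(pts)
        b = fit_h_mechanistic(pts, weights=np.full(len(pts), 2.5))
        assert a.params.k1 == pytest.approx(b.params.k1, rel=1e-6)
        assert a.params.err_max == pytest.approx(b.params.err_max, rel=1e-6)


class TestPolynomialFit:
    def test_exact_quadratic_interpolation(self):
        coef = (13.8, 15.95, -1.1)
        pts = [(x, coef[0] + coef[1] * x + coef[2] * x**2) for x in PANEL_ERRS]
        res = fit_polynomial(pts, 2)
        assert res.coeffs == pytest.approx(coef, abs=1e-9)
        assert res.model is ModelKind.POLY2

    def test_constant_data_degenerates_gracefully(self):
        res = fit_polynomial([(x, 5.0) for x in PANEL_ERRS], 2)
        assert res.coeffs[0] == pytest.approx(5.0)
        assert res.coeffs[1:] == pytest.approx([0.0, 0.0], abs=1e-9)
        assert "constant-response" in res.flags

    def test_unconstrained_cubic_matches_mechanistic_predictions_on_exact_data(self):
        pts = [(e, h_of_err(e)) for e in PANEL_ERRS]
        poly = fit_polynomial(pts, 3)
        mech = fit_h_mechanistic(pts)
        assert poly.predict(PANEL_ERRS) == pytest.approx(mech.predict(PANEL_ERRS), abs=1e-6)

    def test_rank_deficiency_rejected(self):
        with pytest.raises(FitError):
            fit_polynomial([(1.0, 2.0)] * 6, 2)


class TestLogisticFit:
    def test_exact_recovery_on_noiseless_panel(self):
        pts = [(e, g_of_err(e)) for e in PANEL_ERRS]
        res = fit_logistic(pts)
        assert res.params.c0 == pytest.approx(0.5473, abs=1e-4)
        assert res.params.g_max == pytest.approx(10.98, abs=1e-4)
        assert res.params.g_min == pytest.approx(0.8655, abs=1e-4)

    def test_recovered_shape_factor_matches_sigmoid_annotation(self):
        pts = [(e, g_of_err(e)) for e in PANEL_ERRS]
        res = fit_logistic(pts)
        assert res.params.shape_factor == pytest.approx(11.69, abs=0.01)

    def test_shuffle_invariance(self):
        pts = [(e, g_of_err(e) + 0.05 * np.sin(e)) for e in PANEL_ERRS]
        rng = np.random.default_rng(3)
        shuffled = [pts[i] for i in rng.permutation(len(pts))]
        a, b = fit_logistic(pts), fit_logistic(shuffled)
        assert a.params.c0 == pytest.approx(b.params.c0, rel=1e-6)
        assert a.params.g_min == pytest.approx(b.params.g_min, rel=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_logistic([(0, 1), (1, 2), (2, 3)])


class TestLinearFit:
    def test_exact_line(self):
        pts = [(e, -0.3 + 0.623 * e) for e in PANEL_ERRS]
        res = fit_linear(pts)
        assert res.coeffs == pytest.approx([-0.3, 0.623], abs=1e-12)
        assert res.r == pytest.approx(1.0)
        assert res.params.slope == pytest.approx(0.623)

    def test_constant_response_reports_r_zero_with_flag(self):
        res = fit_linear([(e, 4.0) for e in PANEL_ERRS])
        assert res.r == 0.0
        assert "constant-response" in res.flags

    def test_two_point_anticorrelation(self):
        res = fit_linear([(0.0, 1.0), (1.0, 0.0)])
        assert res.coeffs[1] == pytest.approx(-1.0)
        assert res.r == pytest.approx(-1.0)

    def test_constant_x_rejected(self):
        with pytest.raises(FitError):
            fit_linear([(1.0, 0.0), (1.0, 5.0)])


class TestStoredRConsistency:
    def test_r_matches_recomputation_from_observed_and_predicted(self):
        rng = np.random.default_rng(11)
        pts = [(e, h_of_err(e) + rng.normal(0, 3)) for e in PANEL_ERRS]
        for res in (fit_h_mechanistic(pts), fit_polynomial(pts, 3), fit_linear(pts)):
            y = np.array([p[1] for p in pts])
            yhat = res.predict(PANEL_ERRS)
            assert res.r == pytest.approx(stats.pearsonr(y, yhat).statistic, abs=1e-12)


class TestCorrelationScreen:
    def test_perfect_collinearity(self):
        s = correlation_screen([(x, 2 * x + 1) for x in PANEL_ERRS])
        assert s.r == pytest.approx(1.0)
        assert s.significant and s.verdict == "significant"

    def test_zero_variance_flagged_not_raised(self):
        s = correlation_screen([(1, 5), (2, 5), (3, 5)])
        assert not s.significant
        assert "undefined-correlation" in s.flags

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InsufficientDataError):
            correlation_screen([(0, 1), (1, 2)])

    def test_type_i_error_rate_near_alpha(self):
        rng = np.random.default_rng(99)
        hits = sum(
            correlation_screen(list(zip(rng.standard_normal(10), rng.standard_normal(10)))).significant
            for _ in range(400)
        )
        assert 0.02 <= hits / 400 <= 0.09


class TestSmoothedWeights:
    def test_all_zero_sems_give_unit_weights(self):
        w = smoothed_sem_weights([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert np.allclose(w, 1.0)

    def test_weights_decrease_with_mean_under_proportional_noise(self):
        means = np.array([1.0, 5.0, 20.0, 60.0])
        sems = 0.1 * means
        w = smoothed_sem_weights(means, sems)
        assert np.all(np.diff(w) < 0)
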