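"""Mechanistic H(ERR) and logistic G(ERR) models, the composite, and the
ODE cross-checks against the closed forms."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from recombrisk.models import (
    DEFAULT_CALIBRATION,
    DEFAULT_G_PARAMS,
    DEFAULT_H_PARAMS,
    GModelParams,
    HModelParams,
    LinearCalibration,
    NegativePredictionWarning,
    dg_derr,
    dh_derr,
    err_max_from,
    g_of_err,
    h_of_err,
    hg_product,
    integrate_g_ode,
    integrate_h_ode,
    invert_hg,
    k0_from,
    params_from_json,
    params_to_json,
    predict_err,
)


class TestHModel:
    def test_h_at_zero_is_zero(self):
        assert h_of_err(0.0) == 0.0

    def test_h_at_panel_maximum(self):
        # polynomial evaluated independently: 0.3*729 - 4.626*81 + 23.7776*9
        assert h_of_err(9.0) == pytest.approx(57.9928, abs=1e-3)

    def test_h_at_err_max_simplifies(self):
        # substituting err_max into the cubic collapses to k1*err_max^3/12
        p = DEFAULT_H_PARAMS
        assert h_of_err(p.err_max, p) == pytest.approx(p.k1 * p.err_max**3 / 12, rel=1e-12)

    def test_derivative_zero_only_at_half_err_max(self):
        p = DEFAULT_H_PARAMS
        assert dh_derr(p.err_max / 2, p) == pytest.approx(0.0, abs=1e-9)
        grid = np.linspace(0, 2 * p.err_max, 400)
        d = dh_derr(grid, p)
        assert np.all(d >= -1e-9)
        assert d[0] == pytest.approx(p.k0)
        assert dh_derr(p.err_max, p) == pytest.approx(p.k0)  # symmetry of the brake

    def test_k0_constraint_and_inverse(self):
        assert k0_from(0.9, 10.28) == pytest.approx(23.7776, abs=1e-4)
        assert k0_from(1.0, 2.0) == 1.0
        assert err_max_from(23.77, 0.9) == pytest.approx(10.28, abs=0.01)

    def test_negative_err_rejected(self):
        with pytest.raises(ValueError):
            h_of_err(-0.1)

    def test_closed_form_equals_integral_of_derivative(self):
        from scipy.integrate import quad

        p = DEFAULT_H_PARAMS
        for e in (0.5, 3.0, 7.0, 10.0):
            val, _ = quad(lambda u: dh_derr(u, p), 0, e, epsabs=1e-12)
            assert val == pytest.approx(h_of_err(e, p), abs=1e-8)

    @given(st.floats(0, 20), st.floats(0.01, 5), st.floats(0.1, 20))
    @settings(max_examples=100, deadline=None)
    def test_h_nonnegative_and_nondecreasing(self, err, k1, em):
        p = HModelParams(k1=k1, err_max=em)
        assert h_of_err(err, p) >= -1e-9
        assert dh_derr(err, p) >= -1e-9


class TestGModel:
    def test_g_at_zero_is_g_min(self):
        assert g_of_err(0.0) == pytest.approx(DEFAULT_G_PARAMS.g_min, abs=1e-12)

    def test_g_saturates_at_g_max(self):
        assert g_of_err(1e6) == pytest.approx(DEFAULT_G_PARAMS.g_max, rel=1e-9)

    def test_g_at_panel_maximum(self):
        assert g_of_err(9.0) == pytest.approx(10.1215, abs=1e-3)

    def test_shape_factor(self):
        assert DEFAULT_G_PARAMS.shape_factor == pytest.approx(11.69, abs=0.01)

    def test_logistic_rate_fixed_points_and_maximum(self):
        p = DEFAULT_G_PARAMS
        assert dg_derr(0.0, p) == 0.0
        assert dg_derr(p.g_max, p) == pytest.approx(0.0, abs=1e-12)
        assert dg_derr(p.g_max / 2, p) == pytest.approx(p.c0 * p.g_max / 4, rel=1e-12)

    def test_rate_outside_bounds_rejected(self):
        with pytest.raises(ValueError):
            dg_derr(DEFAULT_G_PARAMS.g_max + 1, DEFAULT_G_PARAMS)

    def test_solution_satisfies_logistic_ode(self):
        # analytic derivative of the solution equals c0*G*(1 - G/Gmax)
        p = DEFAULT_G_PARAMS
        grid = np.linspace(0, 12, 500)
        g = g_of_err(grid, p)
        dg_analytic = np.gradient(g, grid)
        assert np.allclose(dg_analytic[1:-1], dg_derr(g, p)[1:-1], atol=2e-3)

    @given(st.floats(0, 50))
    @settings(max_examples=100, deadline=None)
    def test_g_bounded_between_min_and_max(self, err):
        p = DEFAULT_G_PARAMS
        g = g_of_err(err, p)
        assert p.g_min - 1e-12 <= g < p.g_max

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            GModelParams(c0=0.5, g_max=1.0, g_min=2.0)
        with pytest.raises(ValueError):
            GModelParams(c0=-0.5, g_max=10.0, g_min=1.0)


class TestComposite:
    def test_product_zero_at_origin(self):
        assert hg_product(0.0) == 0.0
        assert hg_product(0.0, scale="raw") == 0.0

    def test_percent_scale_is_raw_over_100(self):
        raw = hg_product(9.0, scale="raw")
        assert raw == pytest.approx(586.98, abs=0.05)
        assert hg_product(9.0) == pytest.approx(raw / 100.0)
        assert hg_product(9.0) == pytest.approx(5.8698, abs=5e-4)

    def test_strictly_increasing_on_panel_range(self):
        grid = np.linspace(0, 20, 500)
        vals = hg_product(grid)
        assert np.all(np.diff(vals) > 0)

    def test_unknown_scale_rejected(self):
        with pytest.raises(ValueError):
            hg_product(1.0, scale="permille")


class TestPrediction:
    def test_linear_inversion_of_printed_line(self):
        assert predict_err(5.307) == pytest.approx(9.0, abs=1e-3)

    def test_line_root_maps_to_zero(self):
        assert predict_err(-0.3) == 0.0

    def test_negative_prediction_clamped_with_warning(self):
        with pytest.warns(NegativePredictionWarning):
            assert predict_err(-1.0) == 0.0

    def test_zero_slope_rejected_at_construction(self):
        with pytest.raises(ValueError):
            LinearCalibration(intercept=0.0, slope=0.0)

    @given(st.floats(0, 15))
    @settings(max_examples=100, deadline=None)
    def test_predict_inverts_the_line_exactly(self, err):
        cal = DEFAULT_CALIBRATION
        hg = cal.intercept + cal.slope * err
        assert predict_err(hg, cal) == pytest.approx(err, abs=1e-12)

    @given(st.floats(0.01, 15))
    @settings(max_examples=50, deadline=None)
    def test_invert_hg_is_exact_inverse_of_composite(self, err):
        hg = hg_product(err)
        assert invert_hg(hg) == pytest.approx(err, abs=1e-7)


class TestOdeCrossChecks:
    def test_h_ode_matches_closed_form(self):
        grid = np.arange(0.0, 10.0 + 1e-12, 0.1)
        num = integrate_h_ode(DEFAULT_H_PARAMS, grid)
        assert np.max(np.abs(num - h_of_err(grid, DEFAULT_H_PARAMS))) < 1e-6

    def test_g_ode_matches_closed_form(self):
        grid = np.arange(0.0, 10.0 + 1e-12, 0.1)
        num = integrate_g_ode(DEFAULT_G_PARAMS, grid)
        assert np.max(np.abs(num - g_of_err(grid, DEFAULT_G_PARAMS))) < 1e-6

    def test_zero_k1_gives_identically_zero_h(self):
        p = HModelParams(k1=0.0, err_max=10.0)
        grid = np.arange(0.0, 5.0 + 1e-12, 0.5)
        assert np.allclose(integrate_h_ode(p, grid), 0.0, atol=1e-12)
        assert p.k0 == 0.0

    def test_bad_grid_rejected(self):
        with pytest.raises(ValueError):
            integrate_h_ode(DEFAULT_H_PARAMS, np.array([1.0, 2.0]))


class TestSerialization:
    def test_flat_json_round_trip(self, tmp_path):
        path = tmp_path / "params.json"
        params_to_json(DEFAULT_H_PARAMS, DEFAULT_G_PARAMS, DEFAULT_CALIBRATION, path)
        hp, gp, cal = params_from_json(path)
        assert hp == DEFAULT_H_PARAMS
        assert gp == DEFAULT_G_PARAMS
        assert (cal.intercept, cal.slope, cal.r) == (
            DEFAULT_CALIBRATION.intercept,
            DEFAULT_CALIBRATION.slope,
            DEFAULT_CALIBRATION.r,
        )

    def test_k0_not_stored_independently(self):
        doc = json.loads(params_to_json())
        assert "k0" not in doc
        assert set(doc) >= {"k1", "err_max", "c0", "g_max", "g_min", "cal_intercept", "cal_slope"}
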