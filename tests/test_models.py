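"""Closed-form curve evaluation and derived quantities."""

import math

import numpy as np
import pytest

import lightresponse as lr
from lightresponse.exceptions import (
    DomainError,
    InvalidParameterError,
    NoCompensationPointError,
)

from conftest import random_ye_params

WHEAT_AN = lr.YeParams(0.077, 1.31e-4, 1.02e-3, 3.60)
SOY_AN = lr.YeParams(0.059, 1.40e-4, 5.76e-4, 3.76)
SOY_J = lr.YeParams(0.299, 3.07e-4, -1.50e-4, 0.0)


class TestYePredict:
    def test_zero_irradiance_returns_minus_respiration(self):
        assert lr.ye_predict(WHEAT_AN, 0.0) == pytest.approx(-3.60)
        assert lr.ye_predict(SOY_J, 0.0) == 0.0

    def test_linear_limit(self):
        p = lr.YeParams(0.1, 0.0, 1e-12, 0.0)
        assert lr.ye_predict(p, 500.0) == pytest.approx(50.0, rel=1e-9)

    def test_rational_form_hand_evaluation(self):
        # 0.077*(1-0.131)*1000/(1+1.02) - 3.60 computed by direct arithmetic
        expected = 0.077 * (1 - 1.31e-4 * 1000) * 1000 / (1 + 1.02e-3 * 1000) - 3.60
        assert expected == pytest.approx(29.5252475247, abs=1e-9)
        assert lr.ye_predict(WHEAT_AN, 1000.0) == pytest.approx(expected, rel=1e-12)

    def test_vectorised_over_irradiance(self):
        i = np.array([0.0, 100.0, 1000.0])
        out = lr.ye_predict(WHEAT_AN, i)
        assert out.shape == (3,)
        assert out[2] == pytest.approx(29.5252475247, abs=1e-6)

    def test_domain_error_beyond_validity_window(self):
        p = lr.YeParams(0.1, 5e-4, -4e-4, 0.0)  # valid below I = 2500
        with pytest.raises(DomainError):
            lr.ye_predict(p, 3000.0)
        with pytest.raises(DomainError):
            lr.ye_predict(p, -1.0)


class TestNHPredict:
    def test_blackman_limit_is_exact(self):
        p = lr.NHParams(0.05, 1.0, 20.0, 0.0)
        assert lr.nh_predict(p, 100.0) == 5.0
        assert lr.nh_predict(p, 1000.0) == 20.0
        i = np.linspace(0, 2000, 101)
        expected = np.minimum(0.05 * i, 20.0)
        np.testing.assert_array_equal(lr.nh_predict(p, i), expected)

    def test_zero_irradiance(self):
        p = lr.NHParams(0.05, 0.7, 20.0, 2.5)
        assert lr.nh_predict(p, 0.0) == pytest.approx(-2.5)

    def test_rectangular_hyperbola_limit(self):
        p = lr.NHParams(0.06, 1e-12, 30.0, 0.0)
        rect = 0.06 * 800 * 30.0 / (0.06 * 800 + 30.0)
        assert lr.nh_predict(p, 800.0) == pytest.approx(rect, rel=1e-6)

    def test_monotone_increasing_and_bounded(self):
        rng = np.random.default_rng(7)
        i = np.linspace(0, 3000, 500)
        for _ in range(50):
            p = lr.NHParams(
                rng.uniform(0.02, 0.3), rng.uniform(0.05, 1.0),
                rng.uniform(20, 400), rng.uniform(0, 5),
            )
            y = lr.nh_predict(p, i)
            assert np.all(np.diff(y) > -1e-12)
            assert np.all(y <= p.y_max - p.r_d + 1e-12)


class TestYeDerived:
    def test_brute_force_grid_matches_closed_form(self):
        d = lr.ye_derived(SOY_J)
        grid = np.arange(0.0, 2500.0, 0.1)
        y = lr.ye_predict(SOY_J, grid)
        k = int(np.argmax(y))
        assert abs(grid[k] - d.i_sat) <= 0.1 + 1e-9
        assert y[k] == pytest.approx(d.y_max, rel=1e-6)

    def test_parabola_limit_when_gamma_vanishes(self):
        d = lr.ye_derived(lr.YeParams(0.1, 1e-3, 0.0, 0.0))
        assert d.i_sat == pytest.approx(500.0)
        assert d.y_max == pytest.approx(25.0)

    def test_continuity_in_gamma_at_zero(self):
        base = lr.ye_derived(lr.YeParams(0.1, 1e-3, 0.0, 0.0))
        for g in (1e-12, -1e-12):
            d = lr.ye_derived(lr.YeParams(0.1, 1e-3, g, 0.0))
            assert d.i_sat == pytest.approx(base.i_sat, rel=1e-6)
            assert d.y_max == pytest.approx(base.y_max, rel=1e-6)

    def test_no_photoinhibition_gives_asymptote(self):
        d = lr.ye_derived(lr.YeParams(0.2, 0.0, 1e-3, 1.0))
        assert d.asymptotic
        assert d.i_sat is None
        assert d.y_max == pytest.approx(0.2 / 1e-3 - 1.0)

    def test_invalid_curvature_rejected(self):
        with pytest.raises(InvalidParameterError):
            lr.YeParams(0.1, 1e-4, -2e-4, 0.0)

    def test_maximum_attained_at_saturation_irradiance(self):
        """ye_predict at the closed-form I_sat equals the closed-form maximum."""
        rng = np.random.default_rng(11)
        for _ in range(1000):
            p = random_ye_params(rng, with_rd=rng.random() < 0.5)
            d = lr.ye_derived(p)
            assert lr.ye_predict(p, d.i_sat) == pytest.approx(d.y_max, rel=1e-9, abs=1e-12)

    def test_post_saturation_decline(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            p = random_ye_params(rng)
            d = lr.ye_derived(p)
            if 1 + 2 * p.gamma * d.i_sat > 0:
                assert lr.ye_predict(p, 2 * d.i_sat) < d.y_max


class TestLightCompensation:
    def test_linear_curve_crossing(self):
        p = lr.YeParams(0.1, 0.0, 1e-15, 1.0)
        assert lr.ye_light_compensation(p) == pytest.approx(10.0, rel=1e-9)

    def test_published_soybean_crossing(self):
        assert lr.ye_light_compensation(SOY_AN) == pytest.approx(66.72, rel=0.01)

    def test_root_verified_by_bisection(self):
        from scipy.optimize import brentq

        p = WHEAT_AN
        i_sat = lr.ye_derived(p).i_sat
        root = brentq(lambda i: lr.ye_predict(p, i), 1e-9, i_sat, xtol=1e-10)
        assert lr.ye_light_compensation(p) == pytest.approx(root, rel=1e-9)

    def test_no_crossing_when_respiration_too_large(self):
        p = lr.YeParams(0.01, 1e-3, 1e-4, 10.0)  # y_max < 0
        with pytest.raises(NoCompensationPointError):
            lr.ye_light_compensation(p)

    def test_ordering_below_saturation(self):
        d = lr.ye_derived(SOY_AN)
        assert 0 < d.i_c < d.i_sat

    def test_nh_blackman_case(self):
        p = lr.NHParams(0.05, 1.0, 20.0, 1.0)
        assert lr.nh_light_compensation(p) == pytest.approx(20.0)

    def test_nh_self_consistency(self):
        p = lr.NHParams(0.069, 0.659, 43.30 + 3.29, 3.29)
        ic = lr.nh_light_compensation(p)
        assert lr.nh_predict(p, ic) == pytest.approx(0.0, abs=1e-9)

    def test_nh_degenerate_respiration(self):
        with pytest.raises(NoCompensationPointError):
            lr.nh_light_compensation(lr.NHParams(0.05, 0.8, 3.0, 3.0))


class TestAsymptoteGap:
    def test_blackman_plateau_attained(self):
        p = lr.NHParams(0.5, 1.0, 20.0, 0.0)
        assert lr.nh_asymptote_gap(p, 2000.0) == pytest.approx(0.0, abs=1e-12)

    def test_gap_positive_below_unit_convexity(self):
        p = lr.NHParams(0.3, 0.9, 300.0, 0.0)
        gap = lr.nh_asymptote_gap(p, 2000.0)
        assert gap > 0
        assert gap == pytest.approx(300.0 - lr.nh_predict(p, 2000.0), rel=1e-12)

    def test_rectangular_limit_value(self):
        p = lr.NHParams(0.3, 1e-12, 300.0, 0.0)
        expected = 300.0 * 300.0 / (0.3 * 2000.0 + 300.0)
        assert lr.nh_asymptote_gap(p, 2000.0) == pytest.approx(expected, rel=1e-6)

    def test_gap_positive_across_random_params(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            p = lr.NHParams(
                rng.uniform(0.02, 0.3), rng.uniform(0.05, 0.999), rng.uniform(20, 400)
            )
            assert lr.nh_asymptote_gap(p, rng.uniform(500, 3000)) > 0
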