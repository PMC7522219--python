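"""Nonlinear least-squares estimation for both curve families."""

import numpy as np
import pandas as pd
import pytest

import lightresponse as lr
from lightresponse.exceptions import (
    DegenerateVarianceError,
    InsufficientDataError,
    InvalidParameterError,
)

from conftest import random_nh_params, random_ye_params

SOY_AN = lr.YeParams(0.059, 1.40e-4, 5.76e-4, 3.76)


def make_curve(params, steps, kind, rep="r1", noise=None, rng=None):
    i = np.asarray(steps, dtype=float)
    if isinstance(params, lr.YeParams):
        y = np.asarray(lr.ye_predict(params, i), dtype=float)
    else:
        y = np.asarray(lr.nh_predict(params, i), dtype=float)
    if noise:
        y = y + rng.normal(0, noise * np.max(np.abs(y)), size=y.shape)
    return lr.LightResponseCurve(rep, kind, i, y)


class TestGoodnessOfFit:
    def test_perfect_prediction(self):
        r2, sse, sst = lr.goodness_of_fit([1.0, 2.0, 4.0], [1.0, 2.0, 4.0])
        assert (r2, sse) == (1.0, 0.0)
        assert sst > 0

    def test_mean_prediction_scores_zero(self):
        obs = np.array([1.0, 2.0, 3.0])
        r2, _, _ = lr.goodness_of_fit(obs, np.full(3, obs.mean()))
        assert r2 == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        r2, sse, sst = lr.goodness_of_fit([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])
        assert sse == pytest.approx(1.0)
        assert sst == pytest.approx(2.0)
        assert r2 == pytest.approx(0.5)

    def test_degenerate_variance(self):
        with pytest.raises(DegenerateVarianceError):
            lr.goodness_of_fit([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestCurveValidation:
    def test_too_few_levels(self):
        with pytest.raises(InsufficientDataError):
            lr.LightResponseCurve("r1", "a_n", [0, 100, 200, 300], [0, 1, 2, 3])

    def test_duplicate_irradiances(self):
        with pytest.raises(InvalidParameterError):
            lr.LightResponseCurve("r1", "a_n", [0, 100, 100, 300, 400], [0, 1, 2, 3, 4])

    def test_unknown_kind(self):
        with pytest.raises(InvalidParameterError):
            lr.LightResponseCurve("r1", "gpp", [0, 1, 2, 3, 4], [0, 1, 2, 3, 4])


class TestYeFit:
    def test_noiseless_parameter_recovery(self, soybean_steps):
        res = lr.fit_ye(make_curve(SOY_AN, soybean_steps, "a_n"))
        assert res.converged
        for name in ("alpha", "beta", "gamma", "r_d"):
            assert getattr(res.params, name) == pytest.approx(
                getattr(SOY_AN, name), rel=1e-4
            )

    def test_perfect_linear_data(self):
        i = np.array([0.0, 50.0, 100.0, 200.0, 400.0])
        curve = lr.LightResponseCurve("r1", "a_n", i, 0.05 * i - 1.0)
        res = lr.fit_ye(curve)
        assert res.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_derived_maximum_consistent_with_truth(self, catalog, soybean_steps):
        truth = catalog["gmax_jc"].truth
        res = lr.fit_ye(make_curve(truth, soybean_steps, "j_c"))
        assert res.derived.y_max == pytest.approx(lr.ye_derived(truth).y_max, rel=1e-3)

    def test_electron_curves_fit_through_origin(self, catalog, soybean_steps):
        res = lr.fit_ye(make_curve(catalog["gmax_j"].truth, soybean_steps, "j"))
        assert res.params.r_d == 0.0

    def test_pinned_respiration(self, soybean_steps):
        res = lr.fit_ye(make_curve(SOY_AN, soybean_steps, "a_n"), fix_rd=3.76)
        assert res.params.r_d == 3.76
        assert res.params.alpha == pytest.approx(0.059, rel=1e-6)
        assert res.param_se is not None and "r_d" not in res.param_se


class TestNHFit:
    def test_noiseless_parameter_recovery(self, soybean_steps):
        truth = lr.NHParams(0.282, 0.924, 373.87, 0.0)
        res = lr.fit_nh(make_curve(truth, soybean_steps, "j"))
        assert res.converged
        for name in ("alpha", "theta", "y_max"):
            assert getattr(res.params, name) == pytest.approx(
                getattr(truth, name), rel=1e-4
            )

    def test_theta_at_blackman_boundary(self, soybean_steps):
        truth = lr.NHParams(0.05, 1.0, 30.0, 0.0)
        res = lr.fit_nh(make_curve(truth, soybean_steps, "j"))
        assert res.converged
        assert res.params.theta == pytest.approx(1.0, abs=1e-6)

    def test_asymptote_overestimates_nonasymptotic_truth(self, soybean_steps):
        """Fitting the hyperbola to photoinhibited data inflates the maximum."""
        true_max = lr.ye_derived(SOY_AN).y_max
        res = lr.fit_nh(make_curve(SOY_AN, soybean_steps, "a_n"))
        assert res.derived.y_max > true_max
        assert res.derived.i_sat is None

    def test_reported_maximum_is_net_of_respiration(self, soybean_steps):
        res = lr.fit_nh(make_curve(SOY_AN, soybean_steps, "a_n"))
        assert res.derived.y_max == pytest.approx(
            res.params.y_max - res.params.r_d, rel=1e-12
        )


class TestFitResult:
    def test_r_squared_reproducible_from_residuals(self, soybean_steps):
        rng = np.random.default_rng(2)
        curve = make_curve(SOY_AN, soybean_steps, "a_n", noise=0.02, rng=rng)
        for res in (lr.fit_ye(curve), lr.fit_nh(curve)):
            assert res.check_consistency() < 1e-12

    def test_summary_and_predict(self, soybean_steps):
        res = lr.fit_ye(make_curve(SOY_AN, soybean_steps, "a_n"))
        text = res.summary()
        assert "alpha" in text and "R^2" in text
        assert res.predict(0.0) == pytest.approx(-res.params.r_d)

    def test_from_dataframe_constructor(self, soybean_steps):
        df = pd.DataFrame(
            {"i": soybean_steps, "a_n": lr.ye_predict(SOY_AN, soybean_steps)}
        )
        res = lr.YeModel.from_dataframe(df, response="a_n").fit()
        assert res.params.alpha == pytest.approx(0.059, rel=1e-4)


class TestFitAllReplicates:
    def test_identical_curves_give_identical_results(self, soybean_steps):
        curves = [make_curve(SOY_AN, soybean_steps, "a_n", rep=f"r{k}") for k in range(3)]
        results = lr.fit_all_replicates(curves, "ye")
        assert len(results) == 3
        assert len({r.params for r in results}) == 1

    def test_jittered_truths_bracket_truth(self, soybean_steps):
        rng = np.random.default_rng(4)
        curves = []
        for k in range(3):
            f = float(np.exp(rng.normal(0, 0.05)))
            p = lr.YeParams(SOY_AN.alpha * f, SOY_AN.beta, SOY_AN.gamma, SOY_AN.r_d)
            curves.append(make_curve(p, soybean_steps, "a_n", rep=f"r{k}"))
        results = lr.fit_all_replicates(curves, "ye")
        alphas = [r.params.alpha for r in results]
        assert min(alphas) <= SOY_AN.alpha <= max(alphas)

    def test_empty_input_rejected(self):
        with pytest.raises(InsufficientDataError):
            lr.fit_all_replicates([], "ye")

    def test_order_preserved(self, soybean_steps):
        curves = [make_curve(SOY_AN, soybean_steps, "a_n", rep=f"r{k}") for k in range(3)]
        results = lr.fit_all_replicates(curves, "nh")
        assert [r.curve.replicate_id for r in results] == ["r0", "r1", "r2"]


class TestRecoveryAcrossRandomTruths:
    def test_ye_recovery_small_panel(self, soybean_steps):
        """Noiseless refits reach the generating parameters (spot panel; the
        full 100-truth sweep runs in the acceptance suite)."""
        rng = np.random.default_rng(21)
        for _ in range(10):
            truth = random_ye_params(rng, with_rd=True)
            res = lr.fit_ye(make_curve(truth, soybean_steps, "a_n"))
            for name in ("alpha", "beta", "gamma", "r_d"):
                assert getattr(res.params, name) == pytest.approx(
                    getattr(truth, name), rel=1e-4
                ), name

    def test_nh_recovery_small_panel(self, soybean_steps):
        rng = np.random.default_rng(22)
        for _ in range(10):
            truth = random_nh_params(rng)
            res = lr.fit_nh(make_curve(truth, soybean_steps, "j"))
            for name in ("alpha", "theta", "y_max"):
                assert getattr(res.params, name) == pytest.approx(
                    getattr(truth, name), rel=1e-4
                ), name
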