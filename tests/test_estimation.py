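"""Estimating (kappa0, y_sat): linear transform, NLS, bootstrap."""

import numpy as np
import pytest

from satkin import (
    FitFailureError,
    InputError,
    SaturationCurve,
    SaturationModel,
    SimSpec,
    XYDataSet,
    bootstrap_ci,
    fit_linear_transform,
    fit_nls,
    generate,
    linearize,
)
from conftest import random_curves


class TestLinearize:
    def test_noiseless_points_are_collinear(self, curve):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        data = XYDataSet(x=x, y=curve.eval(x))
        xs, t, excluded = linearize(data)
        assert excluded == []
        slope, intercept = np.polyfit(xs, t, 1)
        assert slope == pytest.approx(0.1, rel=1e-12)    # 1/y_sat
        assert intercept == pytest.approx(0.5, rel=1e-12)  # 1/kappa0
        residual = t - (slope * xs + intercept)
        assert np.max(np.abs(residual)) < 1e-14

    def test_origin_excluded_and_recorded(self, curve):
        x = np.array([0.0, 1.0, 2.0, 4.0])
        data = XYDataSet(x=x, y=curve.eval(x))
        xs, t, excluded = linearize(data)
        assert excluded == [0]
        assert xs.size == 3

    def test_nonpositive_y_raises_naming_index(self):
        data = XYDataSet.__new__(XYDataSet)  # bypass container validation
        data.x = np.array([1.0, 2.0, 3.0, 4.0])
        data.y = np.array([0.5, -1.0, 1.5, 2.0])
        data.replicate_ids = None
        with pytest.raises(InputError, match="index 1"):
            linearize(data)

    def test_too_few_points(self, curve):
        data = XYDataSet(x=[1.0, 2.0], y=curve.eval([1.0, 2.0]))
        with pytest.raises(InputError):
            linearize(data)


class TestLinearTransformFit:
    def test_exact_recovery(self, curve):
        x = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        res = fit_linear_transform(XYDataSet(x=x, y=curve.eval(x)))
        assert res.success
        assert res.kappa0 == pytest.approx(2.0, rel=1e-10)
        assert res.y_sat == pytest.approx(10.0, rel=1e-10)

    def test_transform_identity(self, curve):
        """The reported curve is exactly (1/intercept, 1/slope)."""
        data = generate(SimSpec(curve=curve, n_points=10,
                                noise_model="proportional",
                                noise_scale=0.03, seed=5))
        res = fit_linear_transform(data)
        assert res.kappa0 == pytest.approx(1 / res.transform_intercept, rel=1e-14)
        assert res.y_sat == pytest.approx(1 / res.transform_slope, rel=1e-14)

    def test_noisy_recovery_within_10_percent(self, curve):
        data = generate(SimSpec(curve=curve, n_points=12,
                                noise_model="proportional",
                                noise_scale=0.02, seed=1))
        res = fit_linear_transform(data)
        assert res.kappa0 == pytest.approx(2.0, rel=0.10)
        assert res.y_sat == pytest.approx(10.0, rel=0.10)

    def test_non_saturating_data_fail_explicitly(self):
        x = np.linspace(1, 10, 8)
        res = fit_linear_transform(XYDataSet(x=x, y=3 * x))
        assert not res.success
        assert "saturate" in res.message or "non-positive" in res.message
        with pytest.raises(FitFailureError):
            _ = res.kappa0


class TestNLSFit:
    def test_exact_recovery(self, curve):
        x = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        res = fit_nls(XYDataSet(x=x, y=curve.eval(x)))
        assert res.kappa0 == pytest.approx(2.0, rel=1e-8)
        assert res.y_sat == pytest.approx(10.0, rel=1e-8)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_origin_point_retained(self, curve):
        x = np.array([0.0, 1.0, 2.0, 4.0, 8.0])
        res = fit_nls(XYDataSet(x=x, y=curve.eval(x)))
        assert res.n_points_used == 5
        assert res.kappa0 == pytest.approx(2.0, rel=1e-8)

    def test_additive_noise_monte_carlo_unbiased(self, curve):
        """Mean estimates over 200 seeded replicates sit near truth."""
        k0s, yss = [], []
        for seed in range(1, 201):
            data = generate(SimSpec(curve=curve, n_points=12,
                                    noise_model="additive_gaussian",
                                    noise_scale=0.1, seed=seed))
            res = fit_nls(data)
            k0s.append(res.kappa0)
            yss.append(res.y_sat)
        assert np.mean(yss) == pytest.approx(10.0, rel=0.02)
        assert np.mean(k0s) == pytest.approx(2.0, rel=0.05)

    def test_basin_robustness_to_distant_init(self, curve):
        x = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        data = XYDataSet(x=x, y=curve.eval(x))
        far = SaturationCurve(kappa0=200.0, y_sat=10.0)
        res = fit_nls(data, init=far)
        assert res.kappa0 == pytest.approx(2.0, rel=1e-6)
        assert res.y_sat == pytest.approx(10.0, rel=1e-6)

    def test_weight_scheme_validation(self, noiseless_data):
        with pytest.raises(InputError):
            fit_nls(noiseless_data, weights="cauchy")

    def test_weighted_nls_beats_transform_under_proportional_noise(self, curve):
        """Known pathology of the linear transform: at CV = 5% its kappa0
        RMSE exceeds that of 1/y^2-weighted NLS."""
        err_lt, err_nls = [], []
        for seed in range(500):
            data = generate(SimSpec(curve=curve, n_points=12,
                                    noise_model="proportional",
                                    noise_scale=0.05, seed=seed))
            lt = fit_linear_transform(data)
            nls = fit_nls(data, weights="inverse_y_squared")
            if lt.success and nls.success:
                err_lt.append(lt.kappa0 - curve.kappa0)
                err_nls.append(nls.kappa0 - curve.kappa0)
        assert len(err_lt) > 450
        rmse = lambda e: float(np.sqrt(np.mean(np.square(e))))
        assert rmse(err_nls) < rmse(err_lt)


class TestRoundTripAndConsistency:
    def test_zero_noise_round_trip_both_methods(self):
        for c in random_curves(8, seed=11):
            data = generate(SimSpec(curve=c, n_points=10, seed=0))
            for fitter in (fit_linear_transform, fit_nls):
                res = fitter(data)
                assert res.kappa0 == pytest.approx(c.kappa0, rel=1e-8)
                assert res.y_sat == pytest.approx(c.y_sat, rel=1e-8)

    def test_methods_converge_as_noise_vanishes(self, curve):
        gaps = []
        for cv in (0.05, 0.01, 0.002):
            data = generate(SimSpec(curve=curve, n_points=12,
                                    noise_model="proportional",
                                    noise_scale=cv, seed=9))
            lt, nls = fit_linear_transform(data), fit_nls(data)
            gaps.append(abs(lt.kappa0 - nls.kappa0)
                        + abs(lt.y_sat - nls.y_sat))
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 0.05 * gaps[0]


class TestBootstrap:
    def test_deterministic_given_seed(self, curve):
        data = generate(SimSpec(curve=curve, n_points=12,
                                noise_model="proportional",
                                noise_scale=0.05, seed=3))
        r1 = bootstrap_ci(data, n_boot=199, seed=11)
        r2 = bootstrap_ci(data, n_boot=199, seed=11)
        assert r1.ci_kappa0 == r2.ci_kappa0
        assert r1.ci_ysat == r2.ci_ysat

    def test_noiseless_intervals_degenerate_at_truth(self, curve):
        data = generate(SimSpec(curve=curve, n_points=10, seed=0))
        res = bootstrap_ci(data, n_boot=100, seed=0)
        lo, hi = res.ci_kappa0
        assert lo == pytest.approx(2.0, rel=1e-6)
        assert hi == pytest.approx(2.0, rel=1e-6)

    def test_minimum_resamples_enforced(self, noiseless_data):
        with pytest.raises(InputError):
            bootstrap_ci(noiseless_data, n_boot=50)

    def test_coverage_near_nominal(self, curve):
        """Percentile intervals under noise-matched weights cover the truth
        in >= 90 of 100 outer replicates at nominal 95%."""
        cov_k0 = cov_ys = 0
        for seed in range(100):
            data = generate(SimSpec(curve=curve, n_points=16,
                                    noise_model="proportional",
                                    noise_scale=0.05, seed=1000 + seed))
            res = bootstrap_ci(data, n_boot=199, seed=seed,
                               weights="inverse_y_squared")
            assert res.ci_kappa0 is not None
            cov_k0 += res.ci_kappa0[0] <= 2.0 <= res.ci_kappa0[1]
            cov_ys += res.ci_ysat[0] <= 10.0 <= res.ci_ysat[1]
        assert cov_k0 >= 90
        assert cov_ys >= 90


class TestModelFrontEnd:
    def test_from_dataframe_and_summary(self, curve):
        import pandas as pd

        x = np.array([1.0, 2.0, 4.0, 8.0])
        df = pd.DataFrame({"x": x, "y": curve.eval(x)})
        res = SaturationModel.from_dataframe(df).fit()
        assert res.kappa0 == pytest.approx(2.0, rel=1e-8)
        text = res.summary()
        assert "kappa0" in text and "y_sat" in text

    def test_replicate_preaveraging_option(self, curve):
        data = generate(SimSpec(curve=curve, n_points=8, n_replicates=3,
                                noise_model="proportional",
                                noise_scale=0.02, seed=2))
        raw = SaturationModel(data).fit()
        avg = SaturationModel(data).fit(average_replicates=True)
        assert raw.n_points_used == 24
        assert avg.n_points_used == 8
        assert avg.kappa0 == pytest.approx(raw.kappa0, rel=0.1)

    def test_to_dict_fields(self, noiseless_data):
        d = SaturationModel(noiseless_data).fit().to_dict()
        for key in ("kappa0", "y_sat", "K", "method", "r_squared",
                    "ci_kappa0", "ci_ysat", "excluded_points"):
            assert key in d
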