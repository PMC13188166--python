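import math

import numpy as np
import pytest

from ttraop import bmd as B
from ttraop.synth import GeneratorSpec, gen_dose_response, hill_true_bmd


def _dataset(doses, means, sd=1.0, n=10, direction="decreasing"):
    doses = np.asarray(doses, dtype=float)
    return B.DoseResponseDataset(
        doses=doses, n=np.full(len(doses), n),
        mean=np.asarray(means, dtype=float),
        sd=np.full(len(doses), sd), direction=direction)


def _manual_fit(name, theta, dataset):
    return B.ModelFit(name=name, theta=np.asarray(theta, dtype=float),
                      loglik=0.0, cov=np.eye(len(theta)) * 1e-6,
                      n_params=len(theta), dataset=dataset)


class TestDataset:
    def test_requires_control_and_three_groups(self):
        with pytest.raises(ValueError):
            B.DoseResponseDataset(doses=[1.0, 2.0, 3.0], n=[5, 5, 5],
                                  mean=[1, 2, 3], sd=[1, 1, 1])
        with pytest.raises(ValueError):
            B.DoseResponseDataset(doses=[0.0, 1.0], n=[5, 5],
                                  mean=[1, 2], sd=[1, 1])


class TestFits:
    def test_linear_member_recovers_exact_linear_means(self):
        data = _dataset([0, 2, 4, 8], [50 - 1.5 * d for d in (0, 2, 4, 8)], sd=0.5)
        fits = {f.name: f for f in B.fit_continuous_models(data, suite=["linear"])}
        fit = fits["linear"]
        beta = math.exp(fit.theta[1])
        assert beta == pytest.approx(1.5, abs=1e-6)
        assert fit.mean_response(0.0) == pytest.approx(50.0, abs=1e-6)

    def test_hill_k_recovered_within_thirty_percent_across_seeds(self):
        hits = 0
        for seed in range(20):
            df, truth = gen_dose_response(GeneratorSpec(seed=seed))
            data = B.DoseResponseDataset(df["dose_uM"], df["n"], df["mean"], df["sd"])
            fits = {f.name: f for f in B.fit_continuous_models(data, suite=["hill"])}
            k_hat = math.exp(fits["hill"].theta[2])
            hits += abs(k_hat - truth["params"]["k"]) <= 0.3 * truth["params"]["k"]
        assert hits >= 16

    def test_fitted_curves_monotone_for_decreasing_direction(self):
        df, _ = gen_dose_response(GeneratorSpec(seed=6))
        data = B.DoseResponseDataset(df["dose_uM"], df["n"], df["mean"], df["sd"])
        grid = np.linspace(0, float(data.doses.max()), 200)
        for fit in B.fit_continuous_models(data):
            curve = fit.mean_response(grid)
            assert np.all(np.diff(curve) <= 1e-8)


class TestBMDClosedForms:
    def test_linear_bmd_is_sd_over_slope(self):
        data = _dataset([0, 2, 4, 8], [50, 47, 44, 38], sd=2.0)
        fit = _manual_fit("linear", [50.0, math.log(1.5), math.log(2.0)], data)
        assert B.bmd_from_fit(fit, control_sd=2.0) == pytest.approx(2.0 / 1.5,
                                                                    abs=1e-6)

    def test_hill_unit_shape_bmd_matches_inversion(self):
        # drop v*d/(k+d) with v=10, k=5, sigma0=2 -> bmd = k*sigma0/(v-sigma0)
        data = _dataset([0, 2, 5, 10], [50, 47, 45, 43], sd=2.0)
        th_unit = -30.0   # shape parameter maps to h = 1 within float precision
        fit = _manual_fit("hill", [50.0, math.log(10.0), math.log(5.0), th_unit,
                                   math.log(2.0)], data)
        assert B.bmd_from_fit(fit, control_sd=2.0) == pytest.approx(1.25, abs=1e-6)

    def test_bmd_vanishes_with_control_sd(self):
        data = _dataset([0, 2, 4, 8], [50, 47, 44, 38], sd=2.0)
        fit = _manual_fit("linear", [50.0, math.log(1.5), math.log(2.0)], data)
        assert B.bmd_from_fit(fit, control_sd=1e-9) < 1e-8

    def test_flat_curve_reports_infinite_bmd(self):
        data = _dataset([0, 2, 4, 8], [50, 50, 50, 50], sd=2.0)
        fit = _manual_fit("linear", [50.0, math.log(1e-9), math.log(2.0)], data)
        assert math.isinf(B.bmd_from_fit(fit, control_sd=2.0))


class TestModelAverage:
    def test_single_member_weight_one_and_bmd_near_point_estimate(self):
        df, _ = gen_dose_response(GeneratorSpec(seed=7))
        data = B.DoseResponseDataset(df["dose_uM"], df["n"], df["mean"], df["sd"])
        fits = B.fit_continuous_models(data, suite=["hill"])
        res = B.model_average(fits, n_draws=2000, seed=1)
        assert res.model_weights == {"hill": 1.0}
        point = B.bmd_from_fit(fits[0])
        assert res.bmd == pytest.approx(point, rel=0.15)

    def test_delta_bic_twenty_makes_weight_negligible(self):
        data = _dataset([0, 2, 4, 8], [50, 47, 44, 38], sd=2.0)
        good = _manual_fit("linear", [50.0, math.log(1.5), math.log(2.0)], data)
        bad = _manual_fit("power", [50.0, math.log(1.5), 0.0, math.log(2.0)], data)
        good.loglik = 0.0
        bad.loglik = -10.0   # same k would give dBIC=20; power has one extra param
        bad.n_params = good.n_params
        res = B.model_average([good, bad], n_draws=500, seed=0)
        assert res.model_weights["power"] < 1e-4

    def test_interval_order_is_hard_invariant(self):
        for seed in (11, 12, 13):
            df, _ = gen_dose_response(GeneratorSpec(seed=seed))
            data = B.DoseResponseDataset(df["dose_uM"], df["n"], df["mean"], df["sd"])
            res = B.bmd_analysis(data, n_draws=500, seed=seed)
            assert res.bmdl <= res.bmd <= res.bmdu

    def test_scale_equivariance_in_dose_units(self):
        df, _ = gen_dose_response(GeneratorSpec(seed=14))
        c = 3.0
        data = B.DoseResponseDataset(df["dose_uM"], df["n"], df["mean"], df["sd"])
        scaled = B.DoseResponseDataset(df["dose_uM"] * c, df["n"], df["mean"],
                                       df["sd"])
        a = B.bmd_analysis(data, n_draws=1000, seed=3)
        b = B.bmd_analysis(scaled, n_draws=1000, seed=3)
        assert b.bmd == pytest.approx(c * a.bmd, rel=0.05)
        assert b.bmdl == pytest.approx(c * a.bmdl, rel=0.08)
        assert b.bmdu == pytest.approx(c * a.bmdu, rel=0.08)

    def test_weights_sum_to_one_and_nonnegative(self):
        df, _ = gen_dose_response(GeneratorSpec(seed=15))
        data = B.DoseResponseDataset(df["dose_uM"], df["n"], df["mean"], df["sd"])
        res = B.bmd_analysis(data, n_draws=500, seed=0)
        w = np.array(list(res.model_weights.values()))
        assert np.all(w >= 0) and w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_planted_hill_truth_inside_interval(self):
        spec = GeneratorSpec(seed=16)
        df, truth = gen_dose_response(spec)
        data = B.DoseResponseDataset(df["dose_uM"], df["n"], df["mean"], df["sd"])
        res = B.bmd_analysis(data, n_draws=1000, seed=2)
        assert res.bmdl <= truth["true_bmd_1sd"] <= res.bmdu
        assert truth["true_bmd_1sd"] == pytest.approx(
            hill_true_bmd(spec), abs=1e-12)
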