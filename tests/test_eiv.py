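import numpy as np
import pytest

from ttraop import eiv as E
from ttraop.synth import GeneratorSpec, gen_aop_dataset


def _points(x, y, sx=0.0, sy=0.0):
    x, y = np.asarray(x, float), np.asarray(y, float)
    sx = np.broadcast_to(np.asarray(sx, float), x.shape)
    sy = np.broadcast_to(np.asarray(sy, float), x.shape)
    return [E.AOPDataPoint(f"p{i}", x[i], sx[i], y[i], sy[i])
            for i in range(len(x))]


def _gen_points(seed, **kw):
    df, truth = gen_aop_dataset(GeneratorSpec(seed=seed, **kw))
    pts = [E.AOPDataPoint(str(r["compound"]), r["x_obs"], r["sx"],
                          r["y_obs"], r["sy"]) for _, r in df.iterrows()]
    return pts, truth


class TestFrequentistFit:
    def test_collinear_points_fit_exactly(self):
        x = np.arange(5.0)
        pre = E.frequentist_fit(_points(x, 2.0 * x + 1.0))
        assert pre["slope0"] == pytest.approx(2.0, abs=1e-12)
        assert pre["intercept0"] == pytest.approx(1.0, abs=1e-12)
        assert pre["resid_sd"] == pytest.approx(0.0, abs=1e-9)

    def test_shift_in_response_moves_intercept_only(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=8)
        y = 3.0 * x + rng.normal(0, 1, 8)
        a = E.frequentist_fit(_points(x, y))
        b = E.frequentist_fit(_points(x, y + 10.0))
        assert b["slope0"] == pytest.approx(a["slope0"], abs=1e-12)
        assert b["intercept0"] == pytest.approx(a["intercept0"] + 10.0, abs=1e-10)

    def test_slope_recovered_across_noise_realizations(self):
        good = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.uniform(-10, 10, 8)
            y = 3.0 * x + rng.normal(0, 5, 8)
            good += abs(E.frequentist_fit(_points(x, y))["slope0"] - 3.0) <= 2.0
        assert good >= 18

    def test_zero_predictor_variance_rejected(self):
        with pytest.raises(ValueError):
            E.frequentist_fit(_points(np.ones(5), np.arange(5.0)))


class TestPosterior:
    def test_zero_measurement_error_reduces_to_ols(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(-26, -4, 8)
        y = 103.0 + 3.66 * x + rng.normal(0, 10, 8)
        pts = _points(x, y)
        ols = E.frequentist_fit(pts)["slope0"]
        res = E.fit_eiv(pts, n_draws=6000, warmup=1500, seed=4)
        assert res.slope == pytest.approx(ols, abs=0.05)

    def test_identical_seed_reproduces_draws_bit_exactly(self):
        pts, _ = _gen_points(21)
        a = E.fit_eiv(pts, n_draws=1500, warmup=400, seed=5)
        b = E.fit_eiv(pts, n_draws=1500, warmup=400, seed=5)
        assert np.array_equal(a.draws["b"], b.draws["b"])
        assert np.array_equal(a.draws["a"], b.draws["a"])
        assert a.slope_ci == b.slope_ci

    def test_inflating_response_error_widens_slope_interval(self):
        pts, _ = _gen_points(22)
        wide_pts = [E.AOPDataPoint(p.compound_id, p.x_obs, p.sx, p.y_obs,
                                   10.0 * p.sy) for p in pts]
        narrow = E.fit_eiv(pts, n_draws=2000, warmup=600, seed=6)
        wide = E.fit_eiv(wide_pts, n_draws=2000, warmup=600, seed=6)
        w_n = narrow.slope_ci[1] - narrow.slope_ci[0]
        w_w = wide.slope_ci[1] - wide.slope_ci[0]
        assert w_w > w_n

    def test_doubling_prior_widths_moves_slope_less_than_posterior_sd(self):
        pts, _ = _gen_points(23, aop_sx=1.0)   # well identified
        base_priors = E.build_priors(pts)
        wide_priors = E.EIVPriors(
            slope_center=base_priors.slope_center,
            slope_sd=2 * base_priors.slope_sd,
            intercept_center=base_priors.intercept_center,
            intercept_sd=2 * base_priors.intercept_sd,
            sigma_scale=base_priors.sigma_scale,
            x_center=base_priors.x_center, x_sd=base_priors.x_sd)
        a = E.fit_eiv(pts, priors=base_priors, n_draws=3000, warmup=800, seed=7)
        b = E.fit_eiv(pts, priors=wide_priors, n_draws=3000, warmup=800, seed=7)
        post_sd = np.std(a.draws["b"])
        assert abs(a.slope - b.slope) < post_sd

    def test_prior_assignment_swap_is_supported(self):
        pts, _ = _gen_points(24)
        d = E.build_priors(pts, assignment="default")
        s = E.build_priors(pts, assignment="swap")
        assert d.slope_sd == s.intercept_sd and d.intercept_sd == s.slope_sd
        with pytest.raises(ValueError):
            E.build_priors(pts, assignment="nonsense")

    def test_validity_flag_requires_effective_samples(self):
        pts, _ = _gen_points(25)
        res = E.fit_eiv(pts, n_draws=2000, warmup=600, seed=8)
        assert res.valid
        assert min(res.diagnostics["ess"].values()) >= 100


class TestFitMetrics:
    def test_noiseless_collinear_data_r2_one_rmse_zero(self):
        pts, _ = _gen_points(26, aop_sx=0.0, aop_sy=0.0, aop_sigma=0.0)
        res = E.fit_eiv(pts, n_draws=2000, warmup=600, seed=9)
        assert res.bayes_r2 > 0.99
        assert res.rmse < 0.3

    def test_null_slope_data_gives_near_zero_r2(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(-10, 10, 10)
        y = rng.normal(0, 5, 10)
        res = E.fit_eiv(_points(x, y), n_draws=2000, warmup=600, seed=10)
        assert res.bayes_r2 < 0.1

    def test_rmse_invariant_under_predictor_rescaling(self):
        pts, _ = _gen_points(27)
        scaled = [E.AOPDataPoint(p.compound_id, 10.0 * p.x_obs, 10.0 * p.sx,
                                 p.y_obs, p.sy) for p in pts]
        a = E.fit_eiv(pts, n_draws=3000, warmup=800, seed=11)
        b = E.fit_eiv(scaled, n_draws=3000, warmup=800, seed=11)
        assert b.slope == pytest.approx(a.slope / 10.0, rel=0.1)
        assert b.rmse == pytest.approx(a.rmse, rel=0.1)


class TestLognormalMode:
    def test_lognormal_mode_fits_positive_responses(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(-26, -4, 8)
        y = (103.0 + 3.66 * x) * np.exp(rng.normal(0, 0.2, 8))
        pts = _points(x, y, sx=2.0, sy=1.25)  # sy is a geometric SE factor
        res = E.fit_eiv(pts, n_draws=2000, warmup=600, seed=12,
                        y_error="lognormal")
        assert np.isfinite(res.slope)

    def test_lognormal_mode_rejects_nonpositive_y_and_sub_unit_gse(self):
        pts = _points([-5.0, -10.0, -15.0], [-1.0, 10.0, 20.0], sx=1.0, sy=1.2)
        with pytest.raises(ValueError):
            E.fit_eiv(pts, n_draws=500, warmup=100, seed=0, y_error="lognormal")
        pts2 = _points([-5.0, -10.0, -15.0], [5.0, 10.0, 20.0], sx=1.0, sy=0.5)
        with pytest.raises(ValueError):
            E.fit_eiv(pts2, n_draws=500, warmup=100, seed=0, y_error="lognormal")
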