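"""Bayesian errors-in-variables regression of in vivo PODs on binding energies.

The adverse-outcome-pathway hypothesis is that the free-energy advantage of
PFAS over T4 in binding transthyretin (the molecular initiating event)
controls the in vivo potency of serum-T4 reduction.  Both variables carry
measurement error: the predictor x is an MM-PBSA binding-energy mean with
an SD across replicate simulations, and the response y is a benchmark dose
with a (geometric) standard error from its posterior.

Model (per point i):

    x_obs_i ~ Normal(x_true_i, sx_i)          latent true predictor
    y_obs_i ~ Normal(a + b·x_true_i, sqrt(σ² + sy_i²))      ("normal" mode)
    log y_obs_i ~ Normal(log(a + b·x_true_i), sqrt(σ² + log(sy_i)²))
                                                           ("lognormal" mode)

Priors: a, b normal, centred on a frequentist (OLS) pre-fit with widths
built from the data scales; σ half-Cauchy.  The latent predictors follow a
structural model x_true_i ~ Normal(μ_x, τ²) with the hyperparameters μ_x
and τ estimated jointly (a fixed diffuse latent prior would marginalize to
y ~ N(a + b·x_obs, σ² + sy² + b²·sx²), whose variance term penalizes large
slopes — the classic attenuation inconsistency of functional
errors-in-variables; the structural form is consistent).  The posterior is
sampled with the seeded affine-invariant ensemble sampler (emcee); points
with sx = 0 have their latent x pinned to the observation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import emcee
import numpy as np

log = logging.getLogger(__name__)


@dataclass
class AOPDataPoint:
    compound_id: str
    x_obs: float     # binding energy, kcal/mol
    sx: float        # kcal/mol
    y_obs: float     # BMD, μM
    sy: float        # μM (or geometric SE, per y_error mode)

    def __post_init__(self):
        if self.sx < 0 or self.sy < 0:
            raise ValueError("measurement SDs must be non-negative")


@dataclass
class EIVPriors:
    slope_center: float
    slope_sd: float
    intercept_center: float
    intercept_sd: float
    sigma_scale: float
    x_center: float
    x_sd: float


@dataclass
class EIVRegressionResult:
    slope: float
    slope_ci: tuple[float, float]
    intercept: float
    intercept_ci: tuple[float, float]
    sigma: float
    bayes_r2: float
    rmse: float
    n_draws: int
    diagnostics: dict
    valid: bool
    draws: dict = field(repr=False, default_factory=dict)  # a, b, sigma, x_true


def _arrays(points):
    x = np.array([p.x_obs for p in points], dtype=float)
    sx = np.array([p.sx for p in points], dtype=float)
    y = np.array([p.y_obs for p in points], dtype=float)
    sy = np.array([p.sy for p in points], dtype=float)
    return x, sx, y, sy


def frequentist_fit(points) -> dict:
    """OLS pre-fit ignoring measurement error, plus prior-width summaries.

    Returns the OLS slope/intercept, the SD of the observed predictor and a
    geometric-standard-error summary of the response uncertainties (mean of
    the reported sy when any is positive, else the residual SD).
    """
    x, sx, y, sy = _arrays(points)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the predictor")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    y_scale_error = float(np.mean(sy[sy > 0])) if (sy > 0).any() else \
        float(np.std(resid, ddof=2)) if len(x) > 2 else 1.0
    return {
        "slope0": float(slope),
        "intercept0": float(intercept),
        "sd_x": float(np.std(x, ddof=1)),
        "y_scale_error": y_scale_error,
        "resid_sd": float(np.std(resid, ddof=min(2, len(x) - 1))),
    }


def build_priors(points, assignment: str = "default") -> EIVPriors:
    """Priors centred on the frequentist estimates.

    The prior widths follow the data scales: by ``default`` the slope prior
    SD is the SD of the predictor and the intercept prior SD the geometric
    standard-error summary of the response; ``swap`` exchanges the two
    assignments (the convention is ambiguous and both are supported).
    """
    pre = frequentist_fit(points)
    x, _, y, _ = _arrays(points)
    widths = (pre["sd_x"], pre["y_scale_error"])
    if assignment == "swap":
        widths = widths[::-1]
    elif assignment != "default":
        raise ValueError("assignment must be 'default' or 'swap'")
    slope_sd = max(widths[0], 1e-6)
    intercept_sd = max(widths[1], 1e-6)
    return EIVPriors(
        slope_center=pre["slope0"],
        slope_sd=slope_sd,
        intercept_center=pre["intercept0"],
        intercept_sd=intercept_sd,
        sigma_scale=max(pre["resid_sd"], 1e-3),
        x_center=float(np.mean(x)),
        x_sd=10.0 * max(float(np.std(x, ddof=1)), 1e-6),
    )


class _LogProb:
    """Posterior log-density over (a, b, log σ, μ_x, log τ, free latent x_true)."""

    def __init__(self, x, sx, y, sy, priors: EIVPriors, y_error: str):
        self.x, self.sx, self.y = x, sx, y
        self.priors = priors
        self.y_error = y_error
        self.free = sx > 0
        self.sd_x = max(float(np.std(x, ddof=1)), 1e-6)
        if y_error == "lognormal":
            if np.any(y <= 0):
                raise ValueError("lognormal response mode requires positive y_obs")
            bad = (sy > 0) & (sy < 1)
            if bad.any():
                raise ValueError("geometric SEs must be >= 1 in lognormal mode")
            self.sy_log2 = np.where(sy > 0, np.log(np.clip(sy, 1.0, None)) ** 2, 0.0)
        elif y_error == "normal":
            self.sy2 = sy**2
        else:
            raise ValueError("y_error must be 'normal' or 'lognormal'")

    @property
    def ndim(self) -> int:
        return 5 + int(self.free.sum())

    def initial(self, rng: np.random.Generator, n_walkers: int) -> np.ndarray:
        pr = self.priors
        center = np.concatenate([
            [pr.intercept_center, pr.slope_center, math.log(pr.sigma_scale),
             pr.x_center, math.log(self.sd_x)],
            self.x[self.free],
        ])
        scale = np.concatenate([
            [0.1 * pr.intercept_sd + 1e-8, 0.1 * pr.slope_sd + 1e-8, 0.1,
             0.1 * self.sd_x, 0.1],
            0.1 * np.maximum(self.sx[self.free], 1e-3),
        ])
        return center + scale * rng.standard_normal((n_walkers, len(center)))

    def __call__(self, theta: np.ndarray) -> float:
        a, b, log_sigma, mu_x, log_tau = theta[:5]
        if not -30.0 < log_sigma < 30.0 or not -30.0 < log_tau < 30.0:
            return -np.inf
        sigma = math.exp(log_sigma)
        tau = math.exp(log_tau)
        x_true = self.x.copy()
        x_true[self.free] = theta[5:]
        pr = self.priors
        lp = (
            -0.5 * ((a - pr.intercept_center) / pr.intercept_sd) ** 2
            - 0.5 * ((b - pr.slope_center) / pr.slope_sd) ** 2
            # half-Cauchy on sigma with log-sigma Jacobian
            + math.log(2.0 / (math.pi * pr.sigma_scale
                              * (1.0 + (sigma / pr.sigma_scale) ** 2)))
            + log_sigma
            # hyperpriors of the structural latent-x distribution
            - 0.5 * ((mu_x - pr.x_center) / pr.x_sd) ** 2
            + math.log(2.0 / (math.pi * self.sd_x
                              * (1.0 + (tau / self.sd_x) ** 2)))
            + log_tau
        )
        # structural population model for every latent predictor
        zpop = (x_true - mu_x) / tau
        lp += float(np.sum(-0.5 * zpop**2) - len(x_true) * math.log(tau))
        if self.free.any():
            zx = (self.x[self.free] - x_true[self.free]) / self.sx[self.free]
            lp += float(np.sum(-0.5 * zx**2 - np.log(self.sx[self.free])))
        mu = a + b * x_true
        if self.y_error == "normal":
            var = sigma**2 + self.sy2
            lp += float(np.sum(-0.5 * (self.y - mu) ** 2 / var - 0.5 * np.log(var)))
        else:
            if np.any(mu <= 0):
                return -np.inf
            var = sigma**2 + self.sy_log2
            lp += float(np.sum(-0.5 * (np.log(self.y) - np.log(mu)) ** 2 / var
                               - 0.5 * np.log(var)))
        return lp if math.isfinite(lp) else -np.inf


def fit_eiv(
    points,
    priors: EIVPriors | None = None,
    n_draws: int = 4000,
    seed: int = 0,
    warmup: int = 1000,
    n_walkers: int = 32,
    y_error: str = "normal",
    prior_assignment: str = "default",
) -> EIVRegressionResult:
    """Sample the errors-in-variables posterior with a seeded ensemble MCMC.

    ``n_draws`` is the number of retained posterior draws (pooled over
    walkers) after ``warmup`` steps are discarded.  Validity requires an
    effective sample size of at least 100 for each of a, b and σ.
    """
    x, sx, y, sy = _arrays(points)
    if priors is None:
        priors = build_priors(points, assignment=prior_assignment)
    lp = _LogProb(x, sx, y, sy, priors, y_error)
    ndim = lp.ndim
    n_walkers = max(n_walkers, 2 * ndim + 2)
    steps = warmup + math.ceil(n_draws / n_walkers)

    rng = np.random.default_rng(seed)
    p0 = lp.initial(rng, n_walkers)
    sampler = emcee.EnsembleSampler(n_walkers, ndim, lp)
    sampler.random_state = np.random.RandomState(
        int(rng.integers(2**31 - 1))).get_state()
    sampler.run_mcmc(p0, steps, progress=False)
    chain = sampler.get_chain(discard=warmup, flat=True)
    chain = chain[-n_draws:]

    a_d, b_d, s_d = chain[:, 0], chain[:, 1], np.exp(chain[:, 2])
    x_true_d = np.tile(x, (len(chain), 1))
    if lp.free.any():
        x_true_d[:, lp.free] = chain[:, 5:]

    try:
        tau = sampler.get_autocorr_time(discard=warmup, tol=0, quiet=True)
        n_kept = sampler.get_chain(discard=warmup).shape[0] * n_walkers
        ess = n_kept / np.maximum(tau, 1.0)
    except Exception:  # pragma: no cover - autocorr failure counts as invalid
        ess = np.zeros(ndim)
    ess_core = {"intercept": float(ess[0]), "slope": float(ess[1]),
                "sigma": float(ess[2])}
    valid = min(ess_core.values()) >= 100.0

    fitted_mean = float(np.mean(a_d)) + float(np.mean(b_d)) * x
    rmse = float(np.sqrt(np.mean((y - fitted_mean) ** 2)))

    result = EIVRegressionResult(
        slope=float(np.mean(b_d)),
        slope_ci=(float(np.percentile(b_d, 2.5)), float(np.percentile(b_d, 97.5))),
        intercept=float(np.mean(a_d)),
        intercept_ci=(float(np.percentile(a_d, 2.5)), float(np.percentile(a_d, 97.5))),
        sigma=float(np.mean(s_d)),
        bayes_r2=float("nan"),
        rmse=rmse,
        n_draws=len(chain),
        diagnostics={"ess": ess_core,
                     "acceptance_fraction": float(np.mean(sampler.acceptance_fraction))},
        valid=valid,
        draws={"a": a_d, "b": b_d, "sigma": s_d, "x_true": x_true_d},
    )
    result.bayes_r2 = bayes_r2(result, points)
    return result


def bayes_r2(result: EIVRegressionResult, points) -> float:
    """Bayesian R²: var(fitted)/(var(fitted)+var(residual)), draw-averaged."""
    _, _, y, _ = _arrays(points)
    a_d, b_d = result.draws["a"], result.draws["b"]
    x_true_d = result.draws["x_true"]
    fitted = a_d[:, None] + b_d[:, None] * x_true_d
    var_fit = fitted.var(axis=1)
    var_res = (y[None, :] - fitted).var(axis=1)
    return float(np.mean(var_fit / (var_fit + var_res)))


def rmse(result: EIVRegressionResult, points) -> float:
    """RMSE of the posterior-mean line against observed responses."""
    x, _, y, _ = _arrays(points)
    pred = result.intercept + result.slope * x
    return float(np.sqrt(np.mean((y - pred) ** 2)))
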