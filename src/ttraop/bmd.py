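"""Benchmark-dose modelling for continuous serum-T4 decreases.

Dose-response inputs are group summaries (dose metric in μM serum units,
group size, mean, SD).  Each member of a suite of continuous models
{linear, power, Hill, exponential-3, exponential-5} is fit by maximum
likelihood under a normal, constant-variance likelihood on the summary
statistics.  The benchmark response (BMR) is one standard deviation of the
(modelled) control: the BMD solves |f(BMD) - f(0)| = BMR·σ.

Model uncertainty is propagated by Bayesian model averaging in the
BIC-weight approximation: member weights ∝ exp(-BIC/2), parameters are
drawn from each member's asymptotic normal distribution in proportion to
its weight, a BMD is computed per draw, and the averaged BMD / BMDL / BMDU
are the weighted median and 5th/95th percentiles of the pooled draws.  The
geometric standard error of the BMD draw distribution is reported for use
as the response-side uncertainty in downstream regression.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize
from statsmodels.tools.numdiff import approx_hess

log = logging.getLogger(__name__)

_EXPIT_CAP = 30.0


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -_EXPIT_CAP, _EXPIT_CAP)))


def _shape_param(t):
    """Map an unconstrained value to the (1, 18] shape-exponent range."""
    return 1.0 + 17.0 * _expit(t)


@dataclass
class DoseResponseDataset:
    doses: np.ndarray       # μM (Cmax or TWA serum metric)
    n: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    direction: str = "decreasing"

    def __post_init__(self):
        self.doses = np.asarray(self.doses, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if len(self.doses) < 3 or 0.0 not in self.doses:
            raise ValueError("need >= 3 dose groups including a control (dose 0)")
        if (self.n < 1).any() or (self.sd < 0).any():
            raise ValueError("group n must be >= 1 and SD >= 0")
        if self.direction not in ("decreasing", "increasing"):
            raise ValueError("direction must be 'decreasing' or 'increasing'")

    @property
    def sign(self) -> float:
        return -1.0 if self.direction == "decreasing" else 1.0

    @property
    def control_sd(self) -> float:
        return float(self.sd[self.doses == 0.0][0])


# --------------------------------------------------------------------------
# model suite: each entry maps an unconstrained parameter vector (excluding
# log-sigma, always the last element) to the mean response f(d).

def _mean_linear(d, t, s):
    a, tb = t[..., 0], t[..., 1]
    return a + s * np.exp(tb) * d


def _mean_power(d, t, s):
    a, tb, tg = t[..., 0], t[..., 1], t[..., 2]
    return a + s * np.exp(tb) * np.power(d, _shape_param(tg))


def _mean_hill(d, t, s):
    a, tv, tk, th = t[..., 0], t[..., 1], t[..., 2], t[..., 3]
    v, k, h = np.exp(tv), np.exp(tk), _shape_param(th)
    dh = np.power(d, h)
    return a + s * v * dh / (np.power(k, h) + dh)


def _mean_exp3(d, t, s):
    ta, tb, tg = t[..., 0], t[..., 1], t[..., 2]
    a, b, g = np.exp(ta), np.exp(tb), _shape_param(tg)
    return a * np.exp(s * np.power(b * d, g))


def _mean_exp5(d, t, s):
    ta, tb, tc, tg = t[..., 0], t[..., 1], t[..., 2], t[..., 3]
    a, b, g = np.exp(ta), np.exp(tb), _shape_param(tg)
    if s < 0:                      # decreasing: asymptote fraction c in (0,1)
        c = _expit(tc)
        return a * (c + (1.0 - c) * np.exp(-np.power(b * d, g)))
    c = 1.0 + np.exp(tc)           # increasing: asymptote multiple c > 1
    return a * (c - (c - 1.0) * np.exp(-np.power(b * d, g)))


MODEL_SUITE: dict[str, tuple[Callable, int]] = {
    "linear": (_mean_linear, 2),
    "power": (_mean_power, 3),
    "hill": (_mean_hill, 4),
    "exp3": (_mean_exp3, 3),
    "exp5": (_mean_exp5, 4),
}


@dataclass
class ModelFit:
    name: str
    theta: np.ndarray              # unconstrained, incl. trailing log-sigma
    loglik: float
    cov: np.ndarray                # asymptotic covariance of theta
    n_params: int
    dataset: DoseResponseDataset

    @property
    def sigma(self) -> float:
        return float(np.exp(self.theta[-1]))

    @property
    def bic(self) -> float:
        N = int(self.dataset.n.sum())
        return -2.0 * self.loglik + self.n_params * math.log(N)

    def mean_response(self, d, theta=None) -> np.ndarray:
        t = self.theta if theta is None else theta
        fn = MODEL_SUITE[self.name][0]
        return fn(np.asarray(d, dtype=float), np.asarray(t), self.dataset.sign)


def _nll(theta, data: DoseResponseDataset, mean_fn) -> float:
    sigma = math.exp(min(theta[-1], 50.0))
    f = mean_fn(data.doses, np.asarray(theta), data.sign)
    if not np.all(np.isfinite(f)):
        return 1e12
    ss = (data.n - 1) * data.sd**2 + data.n * (data.mean - f) ** 2
    nll = float(np.sum(data.n) * (math.log(sigma) + 0.5 * math.log(2 * math.pi))
                + np.sum(ss) / (2.0 * sigma**2))
    return nll if math.isfinite(nll) else 1e12


def _starts(name: str, data: DoseResponseDataset) -> np.ndarray:
    m0 = float(data.mean[data.doses == 0.0][0])
    span = max(float(np.ptp(data.mean)), 1e-3)
    dmax = float(data.doses.max())
    dmed = float(np.median(data.doses[data.doses > 0]))
    sd0 = max(float(np.mean(data.sd)), 1e-3)
    ls = math.log(sd0)
    if name == "linear":
        return np.array([m0, math.log(span / dmax), ls])
    if name == "power":
        return np.array([m0, math.log(span / dmax), 0.0, ls])
    if name == "hill":
        return np.array([m0, math.log(span), math.log(dmed), 0.0, ls])
    if name == "exp3":
        return np.array([math.log(max(m0, 1e-3)),
                         math.log(max(span / max(m0, 1e-3), 1e-4) / dmax), 0.0, ls])
    if name == "exp5":
        floor = max(m0 - span, 1e-3) / max(m0, 1e-3)
        tc = math.log(floor / (1 - floor)) if 0 < floor < 1 else 0.0
        return np.array([math.log(max(m0, 1e-3)), math.log(1.0 / dmed), tc, ls])
    raise KeyError(name)


def fit_continuous_models(
    data: DoseResponseDataset,
    suite: Sequence[str] = tuple(MODEL_SUITE),
) -> list[ModelFit]:
    """Maximum-likelihood fits of the model suite on group summaries.

    Non-converging members are dropped with a warning, never silently.
    """
    fits: list[ModelFit] = []
    for name in suite:
        mean_fn, _k = MODEL_SUITE[name]
        try:
            x0 = _starts(name, data)
            res = optimize.minimize(_nll, x0, args=(data, mean_fn),
                                    method="Nelder-Mead",
                                    options={"maxiter": 4000, "xatol": 1e-10,
                                             "fatol": 1e-10})
            res2 = optimize.minimize(_nll, res.x, args=(data, mean_fn),
                                     method="BFGS", options={"maxiter": 500})
            best = res2 if res2.fun <= res.fun else res
            if not math.isfinite(best.fun) or best.fun >= 1e11:
                raise RuntimeError("non-finite objective")
            H = approx_hess(best.x, _nll, args=(data, mean_fn))
            cov = _safe_inverse(H)
            fits.append(ModelFit(name=name, theta=np.asarray(best.x),
                                 loglik=-float(best.fun), cov=cov,
                                 n_params=len(best.x), dataset=data))
        except Exception as exc:  # noqa: BLE001 - member dropped, not silent
            log.warning("model %s dropped: %s", name, exc)
    return fits


def _safe_inverse(H: np.ndarray) -> np.ndarray:
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(H)
        if np.all(np.isfinite(cov)) and np.all(np.diag(cov) > 0):
            return cov
    except np.linalg.LinAlgError:
        pass
    # regularize an ill-conditioned Hessian
    w, V = np.linalg.eigh(H)
    w = np.clip(w, 1e-8, None)
    return (V / w) @ V.T


# --------------------------------------------------------------------------
# BMD solving

def bmd_from_fit(
    fit: ModelFit,
    bmr_sd: float = 1.0,
    control_sd: float | None = None,
    use_sample_control_sd: bool = False,
) -> float:
    """BMD solving |f(bmd) - f(0)| = bmr_sd·σ by bisection.

    σ is the modelled constant SD by default; ``use_sample_control_sd``
    switches to the observed control-group SD, and an explicit
    ``control_sd`` overrides both.  Returns inf when no solution exists in
    [0, 10·d_max].
    """
    if control_sd is None:
        control_sd = fit.dataset.control_sd if use_sample_control_sd else fit.sigma
    if not control_sd > 0:
        raise ValueError("control SD must be positive")
    target = bmr_sd * control_sd
    dmax = float(fit.dataset.doses.max())
    fn = MODEL_SUITE[fit.name][0]
    f = lambda d, t: fn(d, t, fit.dataset.sign)
    return float(_bisect_bmd(f, fit.theta[None, :], np.array([target]), dmax)[0])


def _bisect_bmd(f, thetas: np.ndarray, targets: np.ndarray,
                dmax: float, iters: int = 80) -> np.ndarray:
    """Vectorized bisection of |f(d)-f(0)| = target over parameter draws.

    ``f(d, thetas)`` must broadcast elementwise over the draw axis.
    """
    m = thetas.shape[0]
    f_at = lambda d: f(d, thetas)
    f0 = f_at(np.zeros(m))
    hi = np.full(m, 10.0 * dmax)
    lo = np.zeros(m)
    g_hi = np.abs(f_at(hi) - f0) - targets
    unsolvable = g_hi < 0
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        g_mid = np.abs(f_at(mid) - f0) - targets
        below = g_mid < 0
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    out = 0.5 * (lo + hi)
    out[unsolvable] = np.inf
    return out


# --------------------------------------------------------------------------
# model averaging

@dataclass
class BMDResult:
    bmd: float                     # μM, weighted posterior median
    bmdl: float                    # 5th percentile
    bmdu: float                    # 95th percentile
    bmr_spec: str
    model_weights: dict[str, float]
    per_model_bmds: dict[str, float]
    gse: float                     # geometric SE of the BMD draw distribution
    n_draws: int


def model_average(
    fits: Sequence[ModelFit],
    n_draws: int = 2000,
    seed: int = 0,
    bmr_sd: float = 1.0,
) -> BMDResult:
    """BIC-weighted model-averaged BMD with asymptotic-normal parameter draws."""
    if not fits:
        raise ValueError("no converged fits to average")
    bics = np.array([f.bic for f in fits])
    w = np.exp(-(bics - bics.min()) / 2.0)
    w /= w.sum()
    rng = np.random.default_rng(seed)
    alloc = rng.multinomial(n_draws, w)

    draws: list[np.ndarray] = []
    dmax = float(fits[0].dataset.doses.max())
    for fit, m in zip(fits, alloc):
        if m == 0:
            continue
        try:
            L = np.linalg.cholesky(fit.cov)
        except np.linalg.LinAlgError:
            L = np.diag(np.sqrt(np.clip(np.diag(fit.cov), 1e-12, None)))
        thetas = fit.theta + rng.standard_normal((m, len(fit.theta))) @ L.T
        sigmas = np.exp(np.clip(thetas[:, -1], -30, 30))
        targets = bmr_sd * sigmas
        fn = MODEL_SUITE[fit.name][0]
        f = lambda d, t, s=fit.dataset.sign, fn=fn: fn(d, t, s)
        draws.append(_bisect_bmd(f, thetas, targets, dmax))
    pooled = np.concatenate(draws)
    finite = pooled[np.isfinite(pooled) & (pooled > 0)]
    if finite.size == 0:
        raise ValueError("all BMD draws were non-finite")
    return BMDResult(
        bmd=float(np.median(pooled)),
        bmdl=float(np.percentile(pooled, 5)),
        bmdu=float(np.percentile(pooled, 95)),
        bmr_spec=f"{bmr_sd:g} control SD",
        model_weights={f.name: float(x) for f, x in zip(fits, w)},
        per_model_bmds={f.name: bmd_from_fit(f, bmr_sd=bmr_sd) for f in fits},
        gse=float(np.exp(np.std(np.log(finite)))),
        n_draws=int(n_draws),
    )


def bmd_analysis(
    data: DoseResponseDataset,
    n_draws: int = 2000,
    seed: int = 0,
    bmr_sd: float = 1.0,
    suite: Sequence[str] = tuple(MODEL_SUITE),
) -> BMDResult:
    """Convenience wrapper: fit the suite and model-average the BMD."""
    fits = fit_continuous_models(data, suite=suite)
    return model_average(fits, n_draws=n_draws, seed=seed, bmr_sd=bmr_sd)
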