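"""Two-tier PLS QSAR for PFAS-hTTR binding with a PCA domain of applicability.

Tier 1 is fit on all active PFAS with the broad descriptor set and predicts
the binding region (weak/medium/strong) of any PFAS.  Tier 2 is fit on the
medium+strong subset only, with the conformer van der Waals energy replacing
the Kier shape index, and refines predictions inside its narrower domain.
Each tier carries its own domain-of-applicability (DoA) model: PCA on the
standardized training descriptors, with the axis-aligned bounding rectangle
of the training scores (plus a configurable margin) as the in-domain region.

PLS is a latent-variable linear model; at full rank it coincides with
ordinary least squares, and with fewer components it shrinks along
low-covariance directions, which suits the strongly collinear size
descriptors used here.  Descriptors are standardized to zero mean / unit
variance before fitting because of their heterogeneous units.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA

from .curation import WEAK_CUT, STRONG_CUT, classify_binder
from .descriptors import MODEL1_DESCRIPTORS, MODEL2_DESCRIPTORS

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# splitting

def stratified_split(
    records: Sequence,
    test_fraction: float = 0.2,
    seed: int = 0,
    test_size: int | None = None,
    strata: Sequence[str] | None = None,
    keep_extremes_in_train: bool = False,
    values: Sequence[float] | None = None,
):
    """Deterministic stratified train/test split.

    Strata default to each record's ``binder_class``.  With ``test_size``
    given, per-stratum test counts follow a largest-remainder allocation to
    hit the exact total (the nominal "80/20" of the source study is a 62/10
    split of 72); otherwise each stratum sends round(test_fraction·n) to
    test.  Strata smaller than 2 go entirely to train with a warning.  With
    ``keep_extremes_in_train`` the records with the extreme ``values``
    (default: pec50) are pinned to the training set so it spans the full
    response range.
    """
    n = len(records)
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    if strata is None:
        strata = [getattr(r, "binder_class") for r in records]
    strata = list(strata)
    rng = np.random.default_rng(seed)

    pinned: set[int] = set()
    if keep_extremes_in_train:
        if values is None:
            values = [getattr(r, "pec50") for r in records]
        vals = np.asarray(values, dtype=float)
        pinned = {int(np.nanargmin(vals)), int(np.nanargmax(vals))}

    by_stratum: dict[str, list[int]] = {}
    for i, s in enumerate(strata):
        by_stratum.setdefault(s, []).append(i)

    labels = sorted(by_stratum)
    counts = {s: len(by_stratum[s]) for s in labels}
    if test_size is not None:
        quota = {s: test_size * counts[s] / n for s in labels}
        alloc = {s: int(math.floor(quota[s])) for s in labels}
        remainder = test_size - sum(alloc.values())
        for s in sorted(labels, key=lambda s: quota[s] - alloc[s], reverse=True):
            if remainder <= 0:
                break
            alloc[s] += 1
            remainder -= 1
    else:
        alloc = {s: int(round(test_fraction * counts[s])) for s in labels}

    test_idx: list[int] = []
    for s in labels:
        members = by_stratum[s]
        if len(members) < 2:
            log.warning("stratum %r has <2 members; assigned to train", s)
            continue
        eligible = [i for i in members if i not in pinned]
        k = min(alloc[s], len(eligible))
        chosen = rng.choice(len(eligible), size=k, replace=False)
        test_idx.extend(eligible[int(c)] for c in chosen)

    test_set = set(test_idx)
    train = [records[i] for i in range(n) if i not in test_set]
    test = [records[i] for i in sorted(test_set)]
    return train, test


# --------------------------------------------------------------------------
# PLS

@dataclass
class PLSModel:
    """A fitted PLS regression with its standardization constants."""

    descriptor_names: list[str]
    x_means: np.ndarray
    x_scales: np.ndarray
    y_mean: float
    y_scale: float
    n_components: int
    coefficients: np.ndarray       # original descriptor units
    intercept: float
    weights: np.ndarray            # x_weights (p × k)
    loadings: np.ndarray           # x_loadings (p × k)
    scores: np.ndarray             # training x_scores (n × k)
    training_metrics: dict = field(default_factory=dict)

    def predict(self, X) -> np.ndarray:
        X = _as_matrix(X, self.descriptor_names)
        return X @ self.coefficients + self.intercept

    def to_dict(self) -> dict:
        return {
            "descriptor_names": list(self.descriptor_names),
            "x_means": self.x_means.tolist(),
            "x_scales": self.x_scales.tolist(),
            "y_mean": self.y_mean,
            "y_scale": self.y_scale,
            "n_components": self.n_components,
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "training_metrics": self.training_metrics,
        }


def _as_matrix(X, names: Sequence[str] | None = None) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        if names is not None:
            X = X[list(names)]
        return X.to_numpy(dtype=float)
    return np.atleast_2d(np.asarray(X, dtype=float))


def fit_pls(
    X,
    y,
    n_components: int,
    descriptor_names: Sequence[str] | None = None,
    compute_loo: bool = True,
) -> PLSModel:
    """Fit a PLS regression on standardized descriptors.

    Zero-variance descriptor columns are dropped with a warning.  Training
    R²/RMSE and (optionally) the leave-one-out Q² are stored in
    ``training_metrics``.
    """
    if descriptor_names is None:
        if isinstance(X, pd.DataFrame):
            descriptor_names = list(X.columns)
        else:
            descriptor_names = [f"x{i}" for i in range(np.atleast_2d(X).shape[1])]
    X = _as_matrix(X, descriptor_names)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < n_components + 2:
        raise ValueError(f"need at least n_components+2={n_components + 2} samples, got {n}")

    scales = X.std(axis=0, ddof=1)
    keep = scales > 0
    if not keep.all():
        dropped = [descriptor_names[i] for i in np.flatnonzero(~keep)]
        log.warning("dropping zero-variance descriptors: %s", dropped)
        descriptor_names = [d for d, k in zip(descriptor_names, keep) if k]
        X = X[:, keep]
        scales = scales[keep]
        p = X.shape[1]
    means = X.mean(axis=0)
    Xs = (X - means) / scales
    y_mean = float(y.mean())
    yc = y - y_mean

    k = min(n_components, p, n - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls = PLSRegression(n_components=k, scale=False)
        pls.fit(Xs, yc)
    coef_std = pls.coef_.ravel()
    coefficients = coef_std / scales
    intercept = y_mean - float(means @ coefficients)

    model = PLSModel(
        descriptor_names=list(descriptor_names),
        x_means=means,
        x_scales=scales,
        y_mean=y_mean,
        y_scale=1.0,
        n_components=k,
        coefficients=coefficients,
        intercept=intercept,
        weights=np.asarray(pls.x_weights_),
        loadings=np.asarray(pls.x_loadings_),
        scores=np.asarray(pls.x_scores_),
    )
    fitted = model.predict(X)
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    model.training_metrics = {
        "r2": 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan"),
        "rmse": math.sqrt(ss_res / n),
    }
    if compute_loo:
        model.training_metrics["q2_loo"] = loo_cv(X, y, k, descriptor_names)
    return model


def evaluate(model: PLSModel, X, y) -> dict:
    """Test-set R² (against the test mean) and RMSE in pEC50 units."""
    X = _as_matrix(X, model.descriptor_names)
    y = np.asarray(y, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("empty test set")
    pred = model.predict(X)
    rmse = float(np.sqrt(np.mean((y - pred) ** 2)))
    if y.size == 1:
        return {"r2": None, "rmse": rmse, "r2_undefined": True}
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum((y - pred) ** 2))
    return {"r2": 1.0 - ss_res / ss_tot, "rmse": rmse}


def loo_cv(X, y, n_components: int, descriptor_names: Sequence[str] | None = None) -> float:
    """Leave-one-out cross-validated Q² = 1 - PRESS/SS_tot."""
    X = _as_matrix(X, descriptor_names)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 5:
        raise ValueError("LOO CV needs at least 5 samples")
    press = 0.0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        m = fit_pls(X[mask], y[mask], n_components, compute_loo=False)
        press += float((y[i] - m.predict(X[i : i + 1])[0]) ** 2)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / ss_tot


def select_n_components(X, y, max_components: int = 5,
                        descriptor_names: Sequence[str] | None = None) -> int:
    """Latent dimension maximizing LOO Q², ties broken toward fewer."""
    X = _as_matrix(X, descriptor_names)
    y = np.asarray(y, dtype=float).ravel()
    upper = min(max_components, X.shape[1], len(y) - 2)
    best_k, best_q2 = 1, -np.inf
    for k in range(1, upper + 1):
        q2 = loo_cv(X, y, k)
        if q2 > best_q2 + 1e-9:
            best_k, best_q2 = k, q2
    return best_k


# --------------------------------------------------------------------------
# domain of applicability

@dataclass
class DoAModel:
    """PCA-based domain of applicability for one tier."""

    descriptor_names: list[str]
    means: np.ndarray
    scales: np.ndarray
    pca_loadings: np.ndarray       # 2 × p
    pca1_variance: float
    pca2_variance: float
    training_scores: np.ndarray    # n × 2
    bounds: np.ndarray             # [[min1, max1], [min2, max2]]
    margin: float = 0.0

    def project(self, x) -> np.ndarray:
        x = _as_matrix(x, self.descriptor_names)
        return ((x - self.means) / self.scales) @ self.pca_loadings.T

    def to_dict(self) -> dict:
        return {
            "descriptor_names": list(self.descriptor_names),
            "means": self.means.tolist(),
            "scales": self.scales.tolist(),
            "pca_loadings": self.pca_loadings.tolist(),
            "pca1_variance": self.pca1_variance,
            "pca2_variance": self.pca2_variance,
            "bounds": self.bounds.tolist(),
            "margin": self.margin,
        }


def fit_doa(X, descriptor_names: Sequence[str] | None = None, margin: float = 0.0) -> DoAModel:
    """PCA (2 axes) on standardized training descriptors; rectangle bounds."""
    if descriptor_names is None and isinstance(X, pd.DataFrame):
        descriptor_names = list(X.columns)
    X = _as_matrix(X, descriptor_names)
    if X.shape[0] < 3:
        raise ValueError("DoA model needs at least 3 training compounds")
    scales = X.std(axis=0, ddof=1)
    for j, s in enumerate(scales):
        if s == 0:
            name = descriptor_names[j] if descriptor_names else f"x{j}"
            raise ValueError(f"degenerate variance in descriptor {name!r}")
    means = X.mean(axis=0)
    Xs = (X - means) / scales
    pca = PCA(n_components=2)
    scores = pca.fit_transform(Xs)
    bounds = np.column_stack([scores.min(axis=0), scores.max(axis=0)])
    return DoAModel(
        descriptor_names=list(descriptor_names) if descriptor_names else
        [f"x{i}" for i in range(X.shape[1])],
        means=means,
        scales=scales,
        pca_loadings=np.asarray(pca.components_),
        pca1_variance=float(pca.explained_variance_ratio_[0]),
        pca2_variance=float(pca.explained_variance_ratio_[1]),
        training_scores=scores,
        bounds=bounds,
        margin=margin,
    )


def in_domain(doa: DoAModel, x, margin: float | None = None):
    """Whether a query falls inside the training score rectangle.

    Returns ``(inside, (pca1, pca2))``; the projection is always reported
    so out-of-domain queries are flagged, never silently suppressed.
    """
    m = doa.margin if margin is None else margin
    s = doa.project(x).ravel()
    widths = doa.bounds[:, 1] - doa.bounds[:, 0]
    lo = doa.bounds[:, 0] - m * widths
    hi = doa.bounds[:, 1] + m * widths
    inside = bool(np.all((s >= lo - 1e-12) & (s <= hi + 1e-12)))
    return inside, (float(s[0]), float(s[1]))


# --------------------------------------------------------------------------
# tiered model

@dataclass
class TieredQSAR:
    """Tier-1 (all actives) and Tier-2 (medium+strong) models plus DoAs."""

    tier1: PLSModel
    doa1: DoAModel
    tier2: PLSModel | None = None
    doa2: DoAModel | None = None
    thresholds: dict = field(default_factory=lambda: {"weak_cut": WEAK_CUT,
                                                      "strong_cut": STRONG_CUT})

    def to_json(self, path=None) -> str:
        payload = {
            "schema": "ttraop.tiered_qsar/1",
            "thresholds": self.thresholds,
            "tier1": self.tier1.to_dict(),
            "doa1": self.doa1.to_dict(),
            "tier2": self.tier2.to_dict() if self.tier2 else None,
            "doa2": self.doa2.to_dict() if self.doa2 else None,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "TieredQSAR":
        """Rebuild a prediction-capable model from the serialized schema.

        Latent-structure matrices are not serialized; the reloaded model
        predicts through its coefficient vector and supports DoA checks.
        """
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)

        def _pls(d):
            return PLSModel(
                descriptor_names=list(d["descriptor_names"]),
                x_means=np.asarray(d["x_means"]),
                x_scales=np.asarray(d["x_scales"]),
                y_mean=d["y_mean"], y_scale=d["y_scale"],
                n_components=d["n_components"],
                coefficients=np.asarray(d["coefficients"]),
                intercept=d["intercept"],
                weights=np.empty((0, 0)), loadings=np.empty((0, 0)),
                scores=np.empty((0, 0)),
                training_metrics=d.get("training_metrics", {}),
            )

        def _doa(d):
            return DoAModel(
                descriptor_names=list(d["descriptor_names"]),
                means=np.asarray(d["means"]), scales=np.asarray(d["scales"]),
                pca_loadings=np.asarray(d["pca_loadings"]),
                pca1_variance=d["pca1_variance"],
                pca2_variance=d["pca2_variance"],
                training_scores=np.empty((0, 2)),
                bounds=np.asarray(d["bounds"]), margin=d.get("margin", 0.0),
            )

        return cls(
            tier1=_pls(payload["tier1"]),
            doa1=_doa(payload["doa1"]),
            tier2=_pls(payload["tier2"]) if payload.get("tier2") else None,
            doa2=_doa(payload["doa2"]) if payload.get("doa2") else None,
            thresholds=payload["thresholds"],
        )


def fit_tiered(
    descriptors: pd.DataFrame,
    pec50: Sequence[float],
    binder_class: Sequence[str],
    n_components: int | None = None,
    max_components: int = 5,
    doa_margin: float = 0.0,
    min_tier2: int = 10,
) -> TieredQSAR:
    """Fit both tiers from a descriptor table of curated actives.

    Tier 1 uses the broad descriptor list on all actives; Tier 2 refits the
    medium+strong subset with E_vdw in place of KierA1.  If the Tier-2
    subset is smaller than ``min_tier2`` the tiered model is returned with
    tier2 absent and a warning.  The latent dimension is selected by LOO-CV
    maximization over 1..max_components unless given explicitly.
    """
    y = np.asarray(pec50, dtype=float)
    cls = np.asarray(binder_class)
    X1 = descriptors[list(MODEL1_DESCRIPTORS)]
    k1 = n_components or select_n_components(X1, y, max_components)
    tier1 = fit_pls(X1, y, k1, MODEL1_DESCRIPTORS)
    doa1 = fit_doa(X1, MODEL1_DESCRIPTORS, margin=doa_margin)

    sub = np.isin(cls, ("medium", "strong"))
    tier2 = doa2 = None
    if int(sub.sum()) >= min_tier2:
        X2 = descriptors.loc[sub, list(MODEL2_DESCRIPTORS)]
        k2 = n_components or select_n_components(X2, y[sub], max_components)
        tier2 = fit_pls(X2, y[sub], k2, MODEL2_DESCRIPTORS)
        doa2 = fit_doa(X2, MODEL2_DESCRIPTORS, margin=doa_margin)
    else:
        log.warning("tier-2 subset too small (%d < %d); tier2 absent",
                    int(sub.sum()), min_tier2)
    return TieredQSAR(tier1=tier1, doa1=doa1, tier2=tier2, doa2=doa2)


def predict_tiered(model: TieredQSAR, descriptor_vector) -> dict:
    """Tandem prediction for one compound.

    Tier 1 always reports a pEC50 and its binder class; Tier 2 reports only
    when the Tier-1 class is medium/strong and the compound lies inside the
    Tier-2 DoA.  Out-of-domain status is flagged, never suppressed.
    """
    if hasattr(descriptor_vector, "as_dict"):
        d = descriptor_vector.as_dict()
    else:
        d = dict(descriptor_vector)
    x1 = pd.DataFrame([d])[list(MODEL1_DESCRIPTORS)]
    p1 = float(model.tier1.predict(x1)[0])
    cls = classify_binder(p1)
    in1, s1 = in_domain(model.doa1, x1)
    out = {
        "pec50_tier1": p1,
        "binder_class": cls,
        "in_doa1": in1,
        "doa1_scores": s1,
        "pec50_tier2": None,
        "in_doa2": None,
    }
    if model.tier2 is not None and d.get("E_vdw") is not None:
        x2 = pd.DataFrame([d])[list(MODEL2_DESCRIPTORS)]
        in2, s2 = in_domain(model.doa2, x2)
        out["in_doa2"] = in2
        out["doa2_scores"] = s2
        if cls in ("medium", "strong") and in2:
            out["pec50_tier2"] = float(model.tier2.predict(x2)[0])
    return out
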