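"""End-to-end pipeline runner with config validation and provenance.

Wires the stages curate → descriptors → qsar → dockcal → tk → bmd → eiv
over flat CSV/JSON artifacts.  Every run directory receives an echo of the
effective config, a manifest with the config hash and stage versions, and
a run log; a failure in any stage halts the run with a stage-named error.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bmd as bmd_mod
from . import curation, docking, eiv, qsar, tk
from .descriptors import descriptor_table

log = logging.getLogger(__name__)

STAGE_ORDER = ("curate", "descriptors", "qsar", "dockcal", "tk", "bmd", "eiv")
STAGE_VERSION = "1"


class PreflightError(RuntimeError):
    """Input validation failed before any stage ran."""


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    binding_csv: str | None = None
    docking_csv: str | None = None
    tk_csv: str | None = None
    dose_response_csv: str | None = None
    aop_csv: str | None = None
    stages: list = field(default_factory=lambda: list(STAGE_ORDER))
    seed: int = 0
    include_hydrogens: bool = False
    conformer_seed: int = 20260921
    weak_cut: float = curation.WEAK_CUT
    strong_cut: float = curation.STRONG_CUT
    test_size: int | None = None
    test_fraction: float = 0.2
    tk_metric: str = "cmax"            # cmax | twa
    bmr_sd: float = 1.0
    bmd_draws: int = 2000
    eiv_y_error: str = "normal"        # normal | lognormal
    eiv_draws: int = 4000
    eiv_prior_assignment: str = "default"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


_REQUIRED_COLUMNS = {
    "binding_csv": {"name", "smiles"},
    "docking_csv": {"score"},
    "tk_csv": {"compound", "half_life_h", "vd_L_per_kg", "mw"},
    "dose_response_csv": {"n", "mean", "sd"},
    "aop_csv": {"x_obs", "sx", "y_obs", "sy"},
}
_STAGE_INPUTS = {
    "curate": ("binding_csv",),
    "descriptors": ("binding_csv",),
    "qsar": ("binding_csv",),
    "dockcal": ("docking_csv",),
    "tk": ("tk_csv",),
    "bmd": ("dose_response_csv",),
    "eiv": ("aop_csv",),
}


def preflight(config: RunConfig) -> None:
    """Validate existence and schema of every input an enabled stage needs."""
    problems = []
    for stage in config.stages:
        if stage not in STAGE_ORDER:
            problems.append(f"unknown stage {stage!r}")
            continue
        for key in _STAGE_INPUTS[stage]:
            path = getattr(config, key)
            if path is None or not Path(path).exists():
                problems.append(f"stage {stage!r}: missing input file {key}={path!r}")
                continue
            cols = set(pd.read_csv(path, nrows=0).columns)
            missing = _REQUIRED_COLUMNS[key] - cols
            if missing:
                problems.append(
                    f"stage {stage!r}: {path} lacks columns {sorted(missing)} "
                    f"(found {sorted(cols)})"
                )
    if problems:
        raise PreflightError("; ".join(problems))


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Execute the enabled stages; returns the run directory."""
    preflight(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))
    manifest = {"config_hash": config.config_hash(),
                "stage_version": STAGE_VERSION, "stages_run": []}
    handler = logging.FileHandler(outdir / "run.log")
    root = logging.getLogger("ttraop")
    root.addHandler(handler)
    try:
        state: dict = {}
        for stage in STAGE_ORDER:
            if stage not in config.stages:
                continue
            try:
                _STAGE_FUNCS[stage](config, outdir, state)
                manifest["stages_run"].append(stage)
            except (PreflightError, KeyboardInterrupt):
                raise
            except Exception as exc:
                raise StageError(stage, str(exc)) from exc
        _dump_json(manifest, outdir / "manifest.json")
    finally:
        root.removeHandler(handler)
        handler.close()
    return outdir


# --------------------------------------------------------------------------
# stages

def _stage_curate(config: RunConfig, outdir: Path, state: dict) -> None:
    records = curation.parse_binding_table(config.binding_csv)
    curated = curation.curate(records)
    curation.write_curated(curated, outdir / "curated.csv")
    state["curated"] = curated
    log.info("curate: %d rows in, %d curated", len(records), len(curated))


def _stage_descriptors(config: RunConfig, outdir: Path, state: dict) -> None:
    curated = state.get("curated")
    if curated is None:
        curated = curation.curate(curation.parse_binding_table(config.binding_csv))
        state["curated"] = curated
    actives = [r for r in curated if r.binder_class != "inactive"]
    desc = descriptor_table(
        [(r.compound_id, r.smiles) for r in actives],
        conformer_seed=config.conformer_seed,
        include_hydrogens=config.include_hydrogens,
    )
    desc.to_csv(outdir / "descriptors.csv")
    state["actives"] = actives
    state["descriptors"] = desc
    log.info("descriptors: %d active compounds", len(actives))


def _stage_qsar(config: RunConfig, outdir: Path, state: dict) -> None:
    if "descriptors" not in state:
        _stage_descriptors(config, outdir, state)
    actives, desc = state["actives"], state["descriptors"]
    train, test = qsar.stratified_split(
        actives, test_fraction=config.test_fraction, seed=config.seed,
        test_size=config.test_size, keep_extremes_in_train=True,
    )
    train_ids = [r.compound_id for r in train]
    test_ids = [r.compound_id for r in test]
    model = qsar.fit_tiered(
        desc.loc[train_ids],
        [r.pec50 for r in train],
        [r.binder_class for r in train],
    )
    model.to_json(outdir / "qsar_model.json")
    metrics = {
        "tier1_training": model.tier1.training_metrics,
        "tier1_test": qsar.evaluate(model.tier1, desc.loc[test_ids],
                                    [r.pec50 for r in test]),
        "n_train": len(train), "n_test": len(test),
    }
    if model.tier2 is not None:
        sub = [r for r in test if r.binder_class in ("medium", "strong")]
        metrics["tier2_training"] = model.tier2.training_metrics
        if len(sub) >= 2:
            metrics["tier2_test"] = qsar.evaluate(
                model.tier2, desc.loc[[r.compound_id for r in sub]],
                [r.pec50 for r in sub])
    _dump_json(metrics, outdir / "qsar_metrics.json")
    state["qsar"] = model


def _stage_dockcal(config: RunConfig, outdir: Path, state: dict) -> None:
    df = pd.read_csv(config.docking_csv)
    if "pec50" not in df.columns and state.get("curated"):
        lookup = {r.name: r.pec50 for r in state["curated"]}
        df["pec50"] = df["name"].map(lookup)
    subset = docking.select_calibration_subset(df)
    cal = docking.fit_calibration(subset)
    cal.to_json(outdir / "docking_calibration.json")
    preds = [dict(compound_id="ADONA-like", score=-5.808,
                  **docking.predict_pec50(cal, -5.808)),
             dict(compound_id="GenX-like", score=-4.770,
                  **docking.predict_pec50(cal, -4.770))]
    pd.DataFrame(preds).to_csv(outdir / "docking_predictions.csv", index=False)
    state["dockcal"] = cal


def _stage_tk(config: RunConfig, outdir: Path, state: dict) -> None:
    tk_table = pd.read_csv(config.tk_csv)
    doses = [0.3, 1.0, 3.0, 10.0, 30.0]
    rows = []
    for _, r in tk_table.iterrows():
        params = tk.TKParameters(
            half_life=float(r["half_life_h"]),
            volume_of_distribution=float(r["vd_L_per_kg"]),
            molecular_weight=float(r["mw"]),
            absorption_rate_ka=float(r["ka_per_h"]) if "ka_per_h" in r and
            not np.isnan(r.get("ka_per_h", np.nan)) else None,
        )
        conv = tk.convert_doses(doses, params)
        conv.insert(0, "compound", r["compound"])
        rows.append(conv)
    pd.concat(rows, ignore_index=True).to_csv(outdir / "serum_metrics.csv", index=False)


def _stage_bmd(config: RunConfig, outdir: Path, state: dict) -> None:
    df = pd.read_csv(config.dose_response_csv)
    dose_col = "dose_uM" if "dose_uM" in df.columns else "dose"
    data = bmd_mod.DoseResponseDataset(
        doses=df[dose_col], n=df["n"], mean=df["mean"], sd=df["sd"])
    result = bmd_mod.bmd_analysis(data, n_draws=config.bmd_draws,
                                  seed=config.seed, bmr_sd=config.bmr_sd)
    _dump_json({
        "bmd_uM": result.bmd, "bmdl_uM": result.bmdl, "bmdu_uM": result.bmdu,
        "bmr_spec": result.bmr_spec, "gse": result.gse,
        "model_weights": result.model_weights,
        "per_model_bmds": result.per_model_bmds,
    }, outdir / "bmd.json")
    state["bmd"] = result


def _stage_eiv(config: RunConfig, outdir: Path, state: dict) -> None:
    df = pd.read_csv(config.aop_csv)
    points = [eiv.AOPDataPoint(str(r.get("compound", i)), float(r["x_obs"]),
                               float(r["sx"]), float(r["y_obs"]), float(r["sy"]))
              for i, r in df.iterrows()]
    result = eiv.fit_eiv(points, n_draws=config.eiv_draws, seed=config.seed,
                         y_error=config.eiv_y_error,
                         prior_assignment=config.eiv_prior_assignment)
    _dump_json({
        "slope": result.slope, "slope_ci": list(result.slope_ci),
        "intercept": result.intercept, "intercept_ci": list(result.intercept_ci),
        "sigma": result.sigma, "bayes_r2": result.bayes_r2, "rmse": result.rmse,
        "n_draws": result.n_draws, "diagnostics": result.diagnostics,
        "valid": result.valid,
    }, outdir / "eiv.json")
    state["eiv"] = result


_STAGE_FUNCS = {
    "curate": _stage_curate,
    "descriptors": _stage_descriptors,
    "qsar": _stage_qsar,
    "dockcal": _stage_dockcal,
    "tk": _stage_tk,
    "bmd": _stage_bmd,
    "eiv": _stage_eiv,
}
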