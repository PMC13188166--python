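"""Calibration of docking scores against measured binding potency.

Docking scores (GBVI/WSA-style, kcal/mol, more negative = stronger
predicted binding) are consumed as an input table; no docking is performed
here.  Score-to-pEC50 correlation is only reliable within the chemical
class the receptor model was built around, so the calibration subset is
restricted to perfluorocarboxylates with 4-8 carbons, where the linear
relation holds.  The fitted line then converts scores for new compounds
(e.g. the replacement PFAS ADONA and GenX) into pEC50 estimates and binder
classes; queries outside the calibration score range are flagged as
extrapolated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from scipy import stats

from .curation import classify_binder
from .descriptors import standardize_structure

_CARBOXYLATE = Chem.MolFromSmarts("[CX3](=[OX1])[OX1-,OX2H1]")
_SULFONATE = Chem.MolFromSmarts("[SX4](=[OX1])(=[OX1])[OX1-,OX2H1]")


@dataclass
class DockingScoreRecord:
    compound_id: str
    score: float                 # kcal/mol
    n_carbons: int | None = None
    head_group: str | None = None  # carboxylate | sulfonate | other
    pec50: float | None = None


@dataclass
class DockingCalibration:
    slope: float                 # pEC50 per kcal/mol
    intercept: float             # pEC50
    r2: float
    n_used: int
    score_min: float
    score_max: float
    subset_rule: str = "PFCA with 4 <= n_C <= 8"

    def to_json(self, path=None) -> str:
        text = json.dumps(self.__dict__, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def annotate_from_smiles(smiles: str) -> tuple[int, str]:
    """(carbon count, head group) derived from a structure."""
    mol = standardize_structure(smiles)
    n_c = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 6)
    if mol.HasSubstructMatch(_CARBOXYLATE):
        head = "carboxylate"
    elif mol.HasSubstructMatch(_SULFONATE):
        head = "sulfonate"
    else:
        head = "other"
    return n_c, head


def select_calibration_subset(df: pd.DataFrame) -> pd.DataFrame:
    """Carboxylates with 4-8 carbons having both a score and a pEC50.

    Missing ``n_carbons``/``head_group`` columns are derived from a
    ``smiles`` column when present.
    """
    df = df.copy()
    if "n_carbons" not in df.columns or "head_group" not in df.columns:
        if "smiles" not in df.columns:
            raise ValueError("need n_carbons/head_group columns or a smiles column")
        ann = df["smiles"].map(annotate_from_smiles)
        df["n_carbons"] = [a[0] for a in ann]
        df["head_group"] = [a[1] for a in ann]
    mask = (
        (df["head_group"] == "carboxylate")
        & df["n_carbons"].between(4, 8)
        & df["score"].notna()
        & df["pec50"].notna()
    )
    subset = df[mask]
    if subset.empty:
        raise ValueError("calibration subset is empty (no C4-C8 carboxylates with data)")
    return subset


def fit_calibration(subset: pd.DataFrame, min_points: int = 3) -> DockingCalibration:
    """Ordinary least squares of pEC50 on docking score."""
    scores = np.asarray(subset["score"], dtype=float)
    pec50 = np.asarray(subset["pec50"], dtype=float)
    if len(scores) < min_points:
        raise ValueError(f"need at least {min_points} points, got {len(scores)}")
    if np.ptp(scores) == 0:
        raise ValueError("zero variance in docking scores")
    res = stats.linregress(scores, pec50)
    return DockingCalibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        n_used=len(scores),
        score_min=float(scores.min()),
        score_max=float(scores.max()),
    )


def predict_pec50(cal: DockingCalibration, score: float) -> dict:
    """pEC50 estimate, binder class and extrapolation flag for a score."""
    p = cal.slope * score + cal.intercept
    return {
        "pec50": float(p),
        "binder_class": classify_binder(p),
        "extrapolated": not (cal.score_min <= score <= cal.score_max),
    }
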