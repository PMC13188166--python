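"""One-compartment first-order toxicokinetics for repeated oral gavage.

Applied doses (mg/kg, one gavage per dosing interval over a study window)
are converted into serum concentration-time profiles by superposition of
single-dose solutions on an hourly grid:

* with an absorption phase:
  C(t) = F·D·ka / (V·(ka-ke)) · (exp(-ke·t) - exp(-ka·t))
* bolus (no absorption phase):
  C(t) = F·D/V · exp(-ke·t)

where ke = ln2 / half-life.  The flip-flop boundary ka = ke is rejected by
default; a switch enables the limiting form F·D·ke·t/V·exp(-ke·t).
Profiles are summarized as Cmax (grid maximum) and TWA (trapezoidal
time-weighted average), both convertible to μM via the molecular weight.
These internal-dose metrics put compounds with very different elimination
half-lives on a common serum scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class TKParameters:
    half_life: float                   # h
    volume_of_distribution: float      # L/kg
    molecular_weight: float            # g/mol
    absorption_rate_ka: float | None = None  # 1/h; None = bolus model
    bioavailability_F: float = 1.0

    def __post_init__(self):
        if not self.half_life > 0:
            raise ValueError("half_life must be positive")
        if not self.volume_of_distribution > 0:
            raise ValueError("volume_of_distribution must be positive")
        if not 0 < self.bioavailability_F <= 1:
            raise ValueError("bioavailability_F must be in (0, 1]")

    @property
    def ke(self) -> float:
        return math.log(2.0) / self.half_life


@dataclass
class DoseRegimen:
    dose: float                 # mg/kg per administration
    interval: float = 24.0      # h
    duration: float = 28.0      # days

    def __post_init__(self):
        if self.dose < 0:
            raise ValueError("dose must be non-negative")
        if not self.interval > 0:
            raise ValueError("interval must be positive")


@dataclass
class SerumProfile:
    times: np.ndarray             # h, 1-h grid
    conc_mg_per_L: np.ndarray
    conc_uM: np.ndarray
    cmax_uM: float
    twa_uM: float


def simulate_serum(
    tk: TKParameters,
    regimen: DoseRegimen,
    allow_ka_equal_ke: bool = False,
    grid_step: float = 1.0,
) -> SerumProfile:
    """Serum profile over the study window by superposition of doses."""
    total_h = regimen.duration * 24.0
    times = np.arange(0.0, total_h + 0.5 * grid_step, grid_step)
    dose_times = np.arange(0.0, total_h, regimen.interval)
    ke = tk.ke
    F, D, V = tk.bioavailability_F, regimen.dose, tk.volume_of_distribution

    dt = times[None, :] - dose_times[:, None]
    active = dt >= 0
    dt = np.where(active, dt, 0.0)
    ka = tk.absorption_rate_ka
    if ka is None:
        contrib = (F * D / V) * np.exp(-ke * dt)
    elif math.isclose(ka, ke, rel_tol=1e-12, abs_tol=0.0):
        if not allow_ka_equal_ke:
            raise ValueError(
                "ka equals ke; enable allow_ka_equal_ke to use the limiting "
                "form C(t) = F*D*ke*t/V * exp(-ke*t)"
            )
        contrib = (F * D * ke / V) * dt * np.exp(-ke * dt)
    else:
        contrib = (F * D * ka / (V * (ka - ke))) * (np.exp(-ke * dt) - np.exp(-ka * dt))
    conc = np.where(active, contrib, 0.0).sum(axis=0)
    conc_uM = conc * 1000.0 / tk.molecular_weight
    return SerumProfile(
        times=times,
        conc_mg_per_L=conc,
        conc_uM=conc_uM,
        cmax_uM=float(conc_uM.max()),
        twa_uM=float(np.trapezoid(conc_uM, times) / (times[-1] - times[0])),
    )


def cmax(profile: SerumProfile) -> float:
    return float(np.max(profile.conc_uM))


def twa(profile: SerumProfile) -> float:
    t = profile.times
    return float(np.trapezoid(profile.conc_uM, t) / (t[-1] - t[0]))


def convert_doses(
    doses,
    tk: TKParameters,
    regimen_template: DoseRegimen | None = None,
) -> pd.DataFrame:
    """Per-dose-group Cmax and TWA (μM) for a list of applied doses."""
    template = regimen_template or DoseRegimen(dose=0.0)
    rows = []
    for d in doses:
        regimen = DoseRegimen(dose=float(d), interval=template.interval,
                              duration=template.duration)
        prof = simulate_serum(tk, regimen)
        rows.append({"dose_mg_per_kg": float(d),
                     "cmax_uM": prof.cmax_uM, "twa_uM": prof.twa_uM})
    return pd.DataFrame(rows)


def convert_dose_table(
    dose_table: pd.DataFrame,
    tk_table: pd.DataFrame,
    regimen_template: DoseRegimen | None = None,
) -> pd.DataFrame:
    """Vectorized conversion for many compounds.

    ``dose_table`` needs columns (compound, dose_mg_per_kg); ``tk_table``
    needs (compound, half_life_h, vd_L_per_kg, mw, [ka_per_h]).  Compounds
    lacking TK parameters are skipped with an explicit log entry.
    """
    tk_by_compound = {str(r["compound"]): r for _, r in tk_table.iterrows()}
    out = []
    for compound, sub in dose_table.groupby("compound", sort=False):
        row = tk_by_compound.get(str(compound))
        if row is None:
            log.warning("compound %s skipped: no TK parameters", compound)
            continue
        ka = row.get("ka_per_h")
        if ka is not None and (isinstance(ka, float) and math.isnan(ka)):
            ka = None
        tk = TKParameters(
            half_life=float(row["half_life_h"]),
            volume_of_distribution=float(row["vd_L_per_kg"]),
            molecular_weight=float(row["mw"]),
            absorption_rate_ka=float(ka) if ka is not None else None,
        )
        conv = convert_doses(sub["dose_mg_per_kg"], tk, regimen_template)
        conv.insert(0, "compound", compound)
        out.append(conv)
    if not out:
        return pd.DataFrame(columns=["compound", "dose_mg_per_kg", "cmax_uM", "twa_uM"])
    return pd.concat(out, ignore_index=True)
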