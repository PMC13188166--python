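"""Curation of PFAS-transthyretin binding tables.

The upstream input is a CSV of T4-displacement potencies (EC50 in μM) for
PFAS against human transthyretin (hTTR).  Curation removes explicit salt
forms, collapses duplicate structures onto the most potent measurement,
converts EC50 to pEC50 = -log10(EC50/μM) and assigns a binder class:

* weak    pEC50 < -0.9
* medium  -0.9 <= pEC50 <= 0.12   (both boundaries inclusive)
* strong  pEC50 > 0.12

Compounds without a usable EC50 are retained as ``inactive`` but are
excluded from all downstream model fitting.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

log = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

WEAK_CUT = -0.9
STRONG_CUT = 0.12

#: Salt forms excluded from modelling (matched on normalized compound name).
DEFAULT_SALT_NAMES = (
    "ammonium perfluorooctanoate",
    "potassium perfluorooctanoate",
    "potassium perfluorooctanesulfonate",
    "potassium perfluorohexanesulfonate",
    "sodium perfluorooctanoate",
    "potassium perfluorobutanesulfonate",
    "perfluorooctanesulfonamide ammonium iodide",
)


class ColumnMappingError(ValueError):
    """A required input column could not be resolved."""


class RowParseError(ValueError):
    """A row-level value could not be parsed; carries the row index."""

    def __init__(self, message: str, row: int):
        super().__init__(message)
        self.row = row


@dataclass
class CompoundRecord:
    """One PFAS with its structure and binding potency."""

    compound_id: str
    name: str
    smiles: str
    ec50: float | None = None          # μM
    pec50: float | None = None         # -log10(EC50/μM)
    binder_class: str = "inactive"     # weak | medium | strong | inactive
    is_salt_form: bool = False
    source_row: int = -1

    def with_potency(self) -> "CompoundRecord":
        """Return a copy with pec50 and binder_class derived from ec50."""
        if self.ec50 is None:
            return replace(self, pec50=None, binder_class="inactive")
        p = ec50_to_pec50(self.ec50)
        return replace(self, pec50=p, binder_class=classify_binder(p))


def ec50_to_pec50(ec50: float) -> float:
    """pEC50 = -log10(EC50 in μM); EC50 must be strictly positive."""
    if not (ec50 > 0):
        raise ValueError(f"EC50 must be positive, got {ec50!r}")
    return -math.log10(ec50)


def classify_binder(pec50: float) -> str:
    """Binder class from pEC50; both class boundaries belong to 'medium'."""
    if not math.isfinite(pec50):
        raise ValueError(f"pEC50 must be finite, got {pec50!r}")
    if pec50 < WEAK_CUT:
        return "weak"
    if pec50 <= STRONG_CUT:
        return "medium"
    return "strong"


def _normalize_name(name: str) -> str:
    return re.sub(r"\s+", " ", str(name)).strip().casefold()


def parse_binding_table(
    path,
    column_map: Mapping[str, str] | None = None,
) -> list[CompoundRecord]:
    """Parse a binding CSV into :class:`CompoundRecord` rows.

    ``column_map`` maps logical names {"name", "smiles", "ec50"} (and the
    optional {"compound_id", "linear_flag"}) to the actual CSV headers.
    Rows with a missing or non-positive EC50 are flagged inactive; rows
    with an unparsable (non-numeric, non-empty) EC50 raise
    :class:`RowParseError`.  When a linear-isomer flag column is mapped,
    only rows flagged linear are retained.
    """
    column_map = dict(column_map or {})
    defaults = {"name": "name", "smiles": "smiles", "ec50": "ec50_uM"}
    for key, default in defaults.items():
        column_map.setdefault(key, default)

    df = pd.read_csv(path)
    for key in ("name", "smiles", "ec50"):
        col = column_map[key]
        if col not in df.columns:
            raise ColumnMappingError(
                f"required column {col!r} (logical {key!r}) not found; "
                f"available: {list(df.columns)}"
            )

    records: list[CompoundRecord] = []
    for i, row in df.iterrows():
        if "linear_flag" in column_map:
            flag = row.get(column_map["linear_flag"], True)
            if not _truthy(flag):
                log.info("row %d dropped: non-linear isomer", i)
                continue
        raw = row[column_map["ec50"]]
        ec50: float | None
        if raw is None or (isinstance(raw, float) and math.isnan(raw)) or str(raw).strip() == "":
            ec50 = None
        else:
            try:
                ec50 = float(raw)
            except (TypeError, ValueError):
                raise RowParseError(f"unparsable EC50 {raw!r} at row {i}", row=int(i))
            if not ec50 > 0:
                log.info("row %d: non-positive EC50 %r flagged inactive", i, raw)
                ec50 = None
        name = str(row[column_map["name"]])
        cid_col = column_map.get("compound_id")
        cid = str(row[cid_col]) if cid_col and cid_col in df.columns else f"c{int(i):03d}"
        rec = CompoundRecord(
            compound_id=cid,
            name=name,
            smiles=str(row[column_map["smiles"]]),
            ec50=ec50,
            source_row=int(i),
        ).with_potency()
        records.append(rec)
    return records


def _truthy(value) -> bool:
    if isinstance(value, str):
        return value.strip().casefold() in {"1", "true", "yes", "y", "linear"}
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return True
    return bool(value)


def remove_salt_forms(
    records: Sequence[CompoundRecord],
    salt_names: Iterable[str] = DEFAULT_SALT_NAMES,
) -> list[CompoundRecord]:
    """Drop records whose name matches a known salt form (case-insensitive)."""
    salts = {_normalize_name(s) for s in salt_names}
    kept: list[CompoundRecord] = []
    for rec in records:
        if _normalize_name(rec.name) in salts:
            log.info("salt form removed: %s", rec.name)
        else:
            kept.append(rec)
    return kept


def _dedup_key(rec: CompoundRecord) -> str:
    if rec.smiles and str(rec.smiles).strip() and str(rec.smiles).lower() != "nan":
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is not None:
            return "smi:" + Chem.MolToSmiles(mol)
    return "name:" + _normalize_name(rec.name)


def deduplicate(records: Sequence[CompoundRecord]) -> list[CompoundRecord]:
    """Collapse duplicate structures, keeping the lowest (most potent) EC50.

    Duplicate detection uses canonical-SMILES equality when a structure is
    parsable, otherwise normalized-name equality.  If every copy in a group
    lacks an EC50 the first copy is kept with a warning.
    """
    groups: dict[str, list[CompoundRecord]] = {}
    order: list[str] = []
    for rec in records:
        key = _dedup_key(rec)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(rec)

    survivors: list[CompoundRecord] = []
    for key in order:
        group = groups[key]
        with_ec50 = [r for r in group if r.ec50 is not None]
        if not with_ec50:
            if len(group) > 1:
                log.warning("duplicate group %r has no EC50; keeping first", key)
            survivors.append(group[0])
            continue
        best = min(with_ec50, key=lambda r: r.ec50)
        if len(group) > 1:
            log.info("duplicate %s: kept EC50 %.4g μM of %d copies",
                     best.name, best.ec50, len(group))
        survivors.append(best)
    return survivors


def curate(
    records: Sequence[CompoundRecord],
    salt_names: Iterable[str] = DEFAULT_SALT_NAMES,
) -> list[CompoundRecord]:
    """Salt removal -> deduplication -> potency attachment, in that order."""
    out = remove_salt_forms(records, salt_names)
    out = deduplicate(out)
    return [r.with_potency() for r in out]


def records_to_frame(records: Sequence[CompoundRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in records],
            "name": [r.name for r in records],
            "smiles": [r.smiles for r in records],
            "ec50_uM": [r.ec50 for r in records],
            "pec50": [r.pec50 for r in records],
            "binder_class": [r.binder_class for r in records],
        }
    )


def write_curated(records: Sequence[CompoundRecord], path) -> None:
    """Write the curated table with appended pec50 / binder_class columns."""
    records_to_frame(records).to_csv(path, index=False)
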