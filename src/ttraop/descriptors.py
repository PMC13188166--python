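"""Molecular descriptors for the tiered TTR-binding QSAR.

The models use a small, named set of 2D/3D descriptors: atom/bond/element
counts, topological polar surface area (TPSA), the Balaban J index, the
count of Lipinski rule violations, the largest eigenvalue of a
logP-weighted Burden-type matrix (GCUT_SLOGP_3), the first alpha-modified
Kier kappa shape index (KierA1), and the van der Waals energy of a
minimized 3D conformer (E_vdw, Tier-2 only).

Structures are standardized first: counterions stripped, carboxylic and
sulfonic acid groups deprotonated at physiological pH.  Counts are
hydrogen-suppressed by default with a switch for hydrogen-inclusive
counting.  E_vdw is the MMFF94 van der Waals term of a conformer embedded
(ETKDG, fixed seed) and minimized with the full force field; it is
reproducible for a fixed seed and faithful in rank order, not in absolute
value, to force-field platforms using other parameterizations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Descriptors, GraphDescriptors, rdMolDescriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

log = logging.getLogger(__name__)

#: Descriptor list for the broad-applicability model (Tier 1).
MODEL1_DESCRIPTORS = (
    "n_C", "a_count", "b_single", "TPSA", "BalabanJ",
    "a_nO", "lip_violation", "GCUT_SLOGP_3", "KierA1",
)
#: Tier 2 swaps the shape index for the conformer van der Waals energy.
MODEL2_DESCRIPTORS = (
    "n_C", "a_count", "b_single", "TPSA", "BalabanJ",
    "a_nO", "lip_violation", "GCUT_SLOGP_3", "E_vdw",
)
ALL_DESCRIPTORS = tuple(dict.fromkeys(MODEL1_DESCRIPTORS + MODEL2_DESCRIPTORS))

# Acid groups deprotonated when pH exceeds the (conservative) pKa bound.
_ACID_RULES = (
    ("[CX3](=O)[OX2H1]", 4.9),   # carboxylic; perfluorinated are far lower
    ("[SX4](=O)(=O)[OX2H1]", 0.0),  # sulfonic
)


class StructureError(ValueError):
    """Raised for unparsable SMILES or failed 3D embedding."""


@dataclass
class DescriptorVector:
    """The named descriptors for one standardized compound."""

    n_C: int
    a_count: int
    b_single: int
    a_nO: int
    TPSA: float              # Å²
    BalabanJ: float
    lip_violation: int       # 0-4
    GCUT_SLOGP_3: float
    KierA1: float
    E_vdw: float | None = None  # kcal/mol; None only in 2D-only mode

    def as_dict(self) -> dict[str, float]:
        d = {k: getattr(self, k) for k in ALL_DESCRIPTORS}
        return d


def standardize_structure(smiles: str, pH: float = 7.0) -> Chem.Mol:
    """Standardize a structure at the given pH.

    Strips counterions (largest organic fragment), deprotonates carboxylic
    and sulfonic acids when the pH exceeds their pKa, and returns the
    canonical molecular graph.  Idempotent: re-standardizing the output
    yields the same canonical SMILES.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"unparsable SMILES: {smiles!r}")
    chooser = rdMolStandardize.LargestFragmentChooser()
    mol = chooser.choose(mol)
    rw = Chem.RWMol(mol)
    for smarts, pka in _ACID_RULES:
        if pH <= pka:
            continue
        patt = Chem.MolFromSmarts(smarts)
        for match in rw.GetSubstructMatches(patt):
            oxygen = rw.GetAtomWithIdx(match[-1])
            if oxygen.GetFormalCharge() == 0 and oxygen.GetTotalNumHs() > 0:
                oxygen.SetFormalCharge(-1)
                oxygen.SetNumExplicitHs(0)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolFromSmiles(Chem.MolToSmiles(out))


def kappa_alpha_1(mol: Chem.Mol) -> float:
    """First alpha-modified Kier kappa shape index.

    KierA1 = (A+α)(A+α-1)² / (P+α)² with A the heavy-atom count, P the
    number of bonds between heavy atoms and α the Hall-Kier covalent-radius
    correction (0 for sp3 carbon; negative for fluorine).
    """
    A = mol.GetNumHeavyAtoms()
    if A < 2:
        raise ValueError("kappa shape index requires at least two heavy atoms")
    P = sum(
        1 for b in mol.GetBonds()
        if b.GetBeginAtom().GetAtomicNum() > 1 and b.GetEndAtom().GetAtomicNum() > 1
    )
    alpha = rdMolDescriptors.CalcHallKierAlpha(mol)
    return (A + alpha) * (A + alpha - 1.0) ** 2 / (P + alpha) ** 2


def gcut_slogp(mol: Chem.Mol) -> tuple[float, float, float, float]:
    """Eigenvalue summaries of a logP-weighted Burden-type matrix.

    Diagonal entries are Crippen atomic logP contributions; off-diagonal
    entries for bonded atom pairs are 0.1·(bond order) with a 0.01 floor.
    Returns (smallest, lower-third, upper-third, largest) sorted
    eigenvalues; the largest is the GCUT_SLOGP_3 descriptor.
    """
    contribs = rdMolDescriptors._CalcCrippenContribs(mol)
    n = mol.GetNumAtoms()
    if n == 0:
        raise ValueError("empty molecule")
    B = np.zeros((n, n))
    for i, (logp, _mr) in enumerate(contribs):
        B[i, i] = logp
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        w = max(0.1 * bond.GetBondTypeAsDouble(), 0.01)
        B[i, j] = B[j, i] = w
    eig = np.sort(np.linalg.eigvalsh(B))
    if n == 1:
        v = float(eig[0])
        return (v, v, v, v)
    idx = [0, round((n - 1) / 3.0), round(2 * (n - 1) / 3.0), n - 1]
    return tuple(float(eig[i]) for i in idx)


def lipinski_violations(mol: Chem.Mol) -> int:
    """Count of violated Lipinski rules (MW, logP, HBD, HBA)."""
    rules = (
        Descriptors.MolWt(mol) > 500.0,
        Crippen.MolLogP(mol) > 5.0,
        rdMolDescriptors.CalcNumHBD(mol) > 5,
        rdMolDescriptors.CalcNumHBA(mol) > 10,
    )
    return int(sum(rules))


def vdw_energy(mol: Chem.Mol, conformer_seed: int = 20260921) -> float:
    """MMFF94 van der Waals energy (kcal/mol) of a minimized 3D conformer.

    The conformer is embedded with ETKDG at a fixed seed and minimized with
    the full MMFF94 force field; the reported energy is the van der Waals
    term alone, evaluated at the minimized geometry.
    """
    molH = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(conformer_seed) % (2**31 - 1)
    cid = AllChem.EmbedMolecule(molH, params)
    if cid < 0:
        # retry with random coordinates before giving up
        params.useRandomCoords = True
        cid = AllChem.EmbedMolecule(molH, params)
    if cid < 0:
        raise StructureError(f"3D embedding failed for {Chem.MolToSmiles(mol)}")
    props = AllChem.MMFFGetMoleculeProperties(molH)
    if props is None:
        raise StructureError(f"MMFF94 parameters unavailable for {Chem.MolToSmiles(mol)}")
    ff = AllChem.MMFFGetMoleculeForceField(molH, props, confId=cid)
    ff.Minimize(maxIts=2000)
    vprops = AllChem.MMFFGetMoleculeProperties(molH)
    vprops.SetMMFFBondTerm(False)
    vprops.SetMMFFAngleTerm(False)
    vprops.SetMMFFStretchBendTerm(False)
    vprops.SetMMFFOopTerm(False)
    vprops.SetMMFFTorsionTerm(False)
    vprops.SetMMFFEleTerm(False)
    vff = AllChem.MMFFGetMoleculeForceField(molH, vprops, confId=cid)
    return float(vff.CalcEnergy())


def compute_descriptors(
    mol: Chem.Mol,
    conformer_seed: int = 20260921,
    include_hydrogens: bool = False,
    three_d: bool = True,
) -> DescriptorVector:
    """Compute the full descriptor vector for a standardized structure.

    ``include_hydrogens`` switches a_count/b_single from the default
    hydrogen-suppressed convention to hydrogen-inclusive counting.  With
    ``three_d=False`` the conformer-dependent E_vdw is skipped (None).
    """
    counted = Chem.AddHs(mol) if include_hydrogens else mol
    a_count = counted.GetNumAtoms()
    b_single = sum(
        1 for b in counted.GetBonds() if b.GetBondType() == Chem.BondType.SINGLE
    )
    vec = DescriptorVector(
        n_C=sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 6),
        a_count=a_count,
        b_single=b_single,
        a_nO=sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 8),
        TPSA=float(Descriptors.TPSA(mol)),
        BalabanJ=float(GraphDescriptors.BalabanJ(mol)),
        lip_violation=lipinski_violations(mol),
        GCUT_SLOGP_3=gcut_slogp(mol)[3],
        KierA1=kappa_alpha_1(mol),
        E_vdw=vdw_energy(mol, conformer_seed) if three_d else None,
    )
    return vec


def descriptor_table(
    smiles_by_id: dict[str, str] | Sequence[tuple[str, str]],
    conformer_seed: int = 20260921,
    include_hydrogens: bool = False,
    three_d: bool = True,
    pH: float = 7.0,
) -> pd.DataFrame:
    """Descriptor DataFrame (rows keyed by compound_id) for many compounds."""
    items = smiles_by_id.items() if isinstance(smiles_by_id, dict) else smiles_by_id
    rows = {}
    for cid, smi in items:
        mol = standardize_structure(smi, pH=pH)
        rows[cid] = compute_descriptors(
            mol, conformer_seed=conformer_seed,
            include_hydrogens=include_hydrogens, three_d=three_d,
        ).as_dict()
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "compound_id"
    return df


def descriptor_table_from_sdf(path, id_property: str = "_Name", **kwargs) -> pd.DataFrame:
    """Descriptor table from an SDF file; compound ids from a mol property."""
    pairs = []
    for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
        if mol is None:
            raise StructureError(f"unparsable SDF record at index {i}")
        cid = mol.GetProp(id_property) if mol.HasProp(id_property) else f"sdf{i:03d}"
        pairs.append((cid, Chem.MolToSmiles(mol)))
    return descriptor_table(pairs, **kwargs)
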