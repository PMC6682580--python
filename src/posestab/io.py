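"""SDF and CSV input/output.

Pose ensembles travel as multi-record V2000 SDF files: every record is
one docked conformation, records of one compound share a compound-id SD
tag, and the docking score sits in a per-record SD tag (Glide's
``r_i_docking_score`` by default).  Reading is delegated to RDKit's SDF
parser; writing uses a fixed-format V2000 emitter so that identical
inputs produce byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger

from .model import ActivityRecord, Atom, Bond, BondGraph, Molecule, PoseEnsemble

logger = logging.getLogger("posestab.io")

COMPOUND_ID_TAG = "compound_id"
SCORE_TAG = "r_i_docking_score"
CHARGE_TAG = "atom.dprop.PartialCharge"

_ORDER_TO_SDF = {1: 1, 2: 2, 3: 3, "ar": 4}
_SDF_TO_ORDER = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: "ar",
}


@dataclass
class SDFReadResult:
    ensembles: list[PoseEnsemble]
    n_records: int = 0
    n_malformed: int = 0
    rejected_compounds: dict[str, str] = field(default_factory=dict)


def read_sdf_ensembles(
    path: str | Path,
    score_tag: str = SCORE_TAG,
    id_tag: str = COMPOUND_ID_TAG,
) -> list[PoseEnsemble]:
    """Read pose ensembles from an SDF file, grouping records by compound id.

    Malformed records are skipped with a logged warning; compounds whose
    records disagree on atom count or element sequence are rejected
    whole.  A missing docking-score tag on any record is an error.
    """
    return read_sdf(path, score_tag=score_tag, id_tag=id_tag).ensembles


def read_sdf(
    path: str | Path,
    score_tag: str = SCORE_TAG,
    id_tag: str = COMPOUND_ID_TAG,
) -> SDFReadResult:
    """Like :func:`read_sdf_ensembles` but returning skip/reject accounting."""
    path = Path(path)
    result = SDFReadResult(ensembles=[])
    if path.stat().st_size == 0:
        return result

    RDLogger.DisableLog("rdApp.*")  # we do our own malformed-record reporting
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)

    grouped: dict[str, list[tuple[Molecule, np.ndarray, float]]] = {}
    order: list[str] = []
    for idx, mol in enumerate(supplier):
        result.n_records += 1
        if mol is None:
            result.n_malformed += 1
            logger.warning("skipping malformed SDF record %d in %s", idx, path)
            continue
        props = mol.GetPropsAsDict()
        cid = str(props.get(id_tag, "")).strip() or (mol.GetProp("_Name") if mol.HasProp("_Name") else "")
        if not cid:
            raise ValueError(f"record {idx}: no compound id (tag {id_tag!r} or title line)")
        if score_tag not in props:
            raise ValueError(f"record {idx} (compound {cid!r}): missing score tag {score_tag!r}")
        score = float(props[score_tag])
        molecule = _mol_from_rdkit(mol, cid, props)
        if cid not in grouped:
            order.append(cid)
        grouped.setdefault(cid, []).append((molecule, molecule.coords, score))

    for cid in order:
        records = grouped[cid]
        first = records[0][0]
        elems = first.elements
        if any(m.elements != elems for m, _, _ in records[1:]):
            msg = "records disagree on atom count or element sequence"
            result.rejected_compounds[cid] = msg
            logger.warning("rejecting compound %r: %s", cid, msg)
            continue
        result.ensembles.append(
            PoseEnsemble(
                molecule=first,
                poses=[xyz for _, xyz, _ in records],
                docking_scores=[s for _, _, s in records],
            )
        )
    return result


def _mol_from_rdkit(mol: Chem.Mol, cid: str, props: dict) -> Molecule:
    conf = mol.GetConformer()
    charges = None
    if CHARGE_TAG in props:
        charges = [float(x) for x in str(props[CHARGE_TAG]).split()]
        if len(charges) != mol.GetNumAtoms():
            raise ValueError(f"compound {cid!r}: charge list length mismatch")
    atoms = []
    for a in mol.GetAtoms():
        pos = conf.GetAtomPosition(a.GetIdx())
        atoms.append(
            Atom(
                element=a.GetSymbol(),
                coords=np.array([pos.x, pos.y, pos.z]),
                partial_charge=None if charges is None else charges[a.GetIdx()],
            )
        )
    bonds = [
        Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _SDF_TO_ORDER.get(b.GetBondType(), 1))
        for b in mol.GetBonds()
    ]
    return Molecule(atoms=atoms, bonds=BondGraph(bonds, len(atoms)), id=cid)


def write_sdf_ensembles(
    ensembles: list[PoseEnsemble],
    path: str | Path,
    score_tag: str = SCORE_TAG,
    id_tag: str = COMPOUND_ID_TAG,
) -> None:
    """Write ensembles as a V2000 SDF, one record per pose.

    Output formatting is fixed (coordinates to 4 decimals, scores to 6)
    so repeated writes of the same data are byte-identical.
    """
    lines: list[str] = []
    for ens in ensembles:
        mol = ens.molecule
        charges = mol.charges
        for rank, (xyz, score) in enumerate(zip(ens.poses, ens.docking_scores)):
            lines.append(f"{mol.id}")
            lines.append("  posestab")
            lines.append("")
            lines.append(
                f"{mol.n_atoms:3d}{len(mol.bonds):3d}  0  0  0  0  0  0  0  0999 V2000"
            )
            for el, (x, y, z) in zip(mol.elements, xyz):
                lines.append(f"{x:10.4f}{y:10.4f}{z:10.4f} {el:<3s} 0  0  0  0  0  0  0  0  0  0  0  0")
            for b in mol.bonds:
                lines.append(f"{b.i + 1:3d}{b.j + 1:3d}{_ORDER_TO_SDF[b.order]:3d}  0")
            lines.append("M  END")
            lines.append(f">  <{id_tag}>")
            lines.append(mol.id)
            lines.append("")
            lines.append(f">  <{score_tag}>")
            lines.append(f"{score:.6f}")
            lines.append("")
            lines.append(">  <pose_rank>")
            lines.append(str(rank))
            lines.append("")
            if charges is not None:
                lines.append(f">  <{CHARGE_TAG}>")
                lines.append(" ".join(f"{q:.6f}" for q in charges))
                lines.append("")
            lines.append("$$$$")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_activity_csv(path: str | Path) -> list[ActivityRecord]:
    """Read activity annotations (columns compound_id, ki_nm, ic50_nm)."""
    df = pd.read_csv(path, dtype={"compound_id": str})
    records = []
    for row in df.itertuples(index=False):
        ki = getattr(row, "ki_nm", None)
        ic50 = getattr(row, "ic50_nm", None)
        records.append(
            ActivityRecord(
                compound_id=row.compound_id,
                ki_nm=None if ki is None or pd.isna(ki) else float(ki),
                ic50_nm=None if ic50 is None or pd.isna(ic50) else float(ic50),
            )
        )
    return records


def write_activity_csv(records: list[ActivityRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in records],
            "ki_nm": [r.ki_nm for r in records],
            "ic50_nm": [r.ic50_nm for r in records],
        }
    ).to_csv(path, index=False)


def to_rdkit(molecule: Molecule) -> Chem.Mol:
    """Build an (unsanitised) RDKit molecule from the internal model."""
    rw = Chem.RWMol()
    for a in molecule.atoms:
        rw.AddAtom(Chem.Atom(a.element))
    bt = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE, "ar": Chem.BondType.AROMATIC}
    for b in molecule.bonds:
        rw.AddBond(b.i, b.j, bt[b.order])
    conf = Chem.Conformer(molecule.n_atoms)
    for i, xyz in enumerate(molecule.coords):
        conf.SetAtomPosition(i, [float(v) for v in xyz])
    mol = rw.GetMol()
    mol.AddConformer(conf)
    mol.SetProp("_Name", molecule.id)
    return mol


def to_smiles(molecule: Molecule) -> str:
    """Line notation for export; no sanitisation, radicals not resolved."""
    mol = to_rdkit(molecule)
    for atom in mol.GetAtoms():
        atom.SetNoImplicit(True)
    return Chem.MolToSmiles(mol, canonical=True)
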