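"""Molecular data model for docking-pose ensembles.

The unit of analysis is a :class:`PoseEnsemble`: one compound together
with up to ten docked conformations and their docking scores (Glide
convention, lower is better).  Atom order is the identity that links
poses, so every pose must share the molecule's element sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np

from .elements import SUPPORTED_ELEMENTS, element_info

BondOrder = Literal[1, 2, 3, "ar"]

MAX_POSES = 10  # docking protocols emit a bounded pose set per ligand


@dataclass
class Atom:
    """A single atom: element symbol, Cartesian coordinates in Angstrom,
    and an optional partial charge (elementary charges) that stays absent
    until computed or read from input."""

    element: str
    coords: np.ndarray
    partial_charge: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError("atom coordinates must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("atom coordinates must be finite")
        if self.element not in SUPPORTED_ELEMENTS:
            element_info(self.element)  # raises UnknownElementError


@dataclass
class Bond:
    i: int
    j: int
    order: BondOrder = 1
    in_ring: bool = False


class BondGraph:
    """Undirected bond list with ring-membership flags.

    Ring flags are recomputed from cycle structure (a bond is in a ring
    iff it is not a bridge of its connected component).
    """

    def __init__(self, bonds: Iterable[Bond], n_atoms: int):
        self.bonds: list[Bond] = list(bonds)
        self.n_atoms = int(n_atoms)
        seen: set[tuple[int, int]] = set()
        for b in self.bonds:
            if b.i == b.j:
                raise ValueError(f"self-loop bond on atom {b.i}")
            if not (0 <= b.i < self.n_atoms and 0 <= b.j < self.n_atoms):
                raise ValueError(f"bond ({b.i},{b.j}) outside atom range")
            key = (min(b.i, b.j), max(b.i, b.j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)
        self._refresh_ring_flags()

    def _refresh_ring_flags(self) -> None:
        g = self.to_networkx()
        bridges = {frozenset(e) for e in nx.bridges(g)}
        for b in self.bonds:
            b.in_ring = frozenset((b.i, b.j)) not in bridges

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from((b.i, b.j) for b in self.bonds)
        return g

    def neighbors(self, idx: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.i == idx:
                out.append(b.j)
            elif b.j == idx:
                out.append(b.i)
        return out

    def __len__(self) -> int:
        return len(self.bonds)

    def __iter__(self):
        return iter(self.bonds)


@dataclass
class Molecule:
    atoms: list[Atom]
    bonds: BondGraph
    id: str = ""

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([element_info(e).mass for e in self.elements])

    @property
    def charges(self) -> np.ndarray | None:
        q = [a.partial_charge for a in self.atoms]
        if any(c is None for c in q):
            return None
        return np.array(q, dtype=float)

    def heavy_mask(self) -> np.ndarray:
        return np.array([e != "H" for e in self.elements], dtype=bool)

    def hybridisations(self) -> list[str]:
        """Per-atom hybridisation class inferred from bond orders: a triple
        bond or two doubles makes sp, any double/aromatic bond sp2, else sp3."""
        kinds = ["sp3"] * self.n_atoms
        double_count = [0] * self.n_atoms
        for b in self.bonds:
            for idx in (b.i, b.j):
                if b.order == 3:
                    kinds[idx] = "sp"
                elif b.order == 2:
                    double_count[idx] += 1
                elif b.order == "ar":
                    if kinds[idx] == "sp3":
                        kinds[idx] = "sp2"
        for idx in range(self.n_atoms):
            if kinds[idx] == "sp":
                continue
            if double_count[idx] >= 2:
                kinds[idx] = "sp"
            elif double_count[idx] == 1 and kinds[idx] == "sp3":
                kinds[idx] = "sp2"
        return kinds


@dataclass
class PoseEnsemble:
    """One compound with its docked conformations.

    ``molecule`` carries topology and reference coordinates; ``poses`` are
    coordinate arrays with identical atom count and order; one docking
    score per pose, lower = better.
    """

    molecule: Molecule
    poses: list[np.ndarray]
    docking_scores: list[float]
    skip_reason: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.poses) <= MAX_POSES:
            raise ValueError(
                f"ensemble must hold between 1 and {MAX_POSES} poses, "
                f"got {len(self.poses)}"
            )
        if len(self.docking_scores) != len(self.poses):
            raise ValueError("one docking score required per pose")
        n = self.molecule.n_atoms
        self.poses = [np.asarray(p, dtype=float) for p in self.poses]
        for p in self.poses:
            if p.shape != (n, 3):
                raise ValueError("every pose must match the molecule's atom count")

    @property
    def compound_id(self) -> str:
        return self.molecule.id

    @property
    def n_poses(self) -> int:
        return len(self.poses)


ActivityLabel = Literal["active", "inactive", "ambiguous"]

ACTIVE_KI_NM = 100.0
INACTIVE_KI_NM = 1000.0


@dataclass
class ActivityRecord:
    compound_id: str
    ki_nm: float | None = None
    ic50_nm: float | None = None
    label: ActivityLabel = field(init=False)

    def __post_init__(self) -> None:
        self.label = label_activity(self.ki_nm, self.ic50_nm)


def label_activity(ki_nm: float | None = None, ic50_nm: float | None = None) -> ActivityLabel:
    """Classify a compound from its binding affinity.

    Active means Ki strictly below 100 nM, inactive strictly above
    1000 nM, anything between (boundaries included) is ambiguous and is
    excluded from group statistics downstream.  When only an IC50 is
    known the effective Ki is IC50/2; an explicit Ki wins over IC50.
    """
    if ki_nm is None and ic50_nm is None:
        raise ValueError("at least one of ki_nm, ic50_nm is required")
    eff = ki_nm if ki_nm is not None else ic50_nm / 2.0
    if eff <= 0:
        raise ValueError(f"affinity must be positive, got {eff} nM")
    if eff < ACTIVE_KI_NM:
        return "active"
    if eff > INACTIVE_KI_NM:
        return "inactive"
    return "ambiguous"


def rotatable_bonds(molecule: Molecule, exclude_amide: bool = False) -> list[Bond]:
    """Bonds satisfying the rotatable definition: acyclic single bonds
    between two heavy atoms that are each bonded to at least one other
    heavy atom.

    ``exclude_amide`` additionally discards C-N bonds where the carbon
    carries a double-bonded oxygen (the usual amide exception some
    toolkits apply); off by default.
    """
    elements = molecule.elements
    heavy_deg = [0] * molecule.n_atoms
    for b in molecule.bonds:
        if elements[b.i] != "H" and elements[b.j] != "H":
            heavy_deg[b.i] += 1
            heavy_deg[b.j] += 1
    out = []
    for b in molecule.bonds:
        if b.order != 1 or b.in_ring:
            continue
        if elements[b.i] == "H" or elements[b.j] == "H":
            continue
        if heavy_deg[b.i] < 2 or heavy_deg[b.j] < 2:
            continue
        if exclude_amide and _is_amide(molecule, b):
            continue
        out.append(b)
    return out


def count_rotatable_bonds(molecule: Molecule, exclude_amide: bool = False) -> int:
    """Number of rotatable bonds (see :func:`rotatable_bonds`)."""
    return len(rotatable_bonds(molecule, exclude_amide=exclude_amide))


def _is_amide(molecule: Molecule, bond: Bond) -> bool:
    el = molecule.elements
    pair = {el[bond.i], el[bond.j]}
    if pair != {"C", "N"}:
        return False
    c_idx = bond.i if el[bond.i] == "C" else bond.j
    for other in molecule.bonds:
        if other.order == 2 and c_idx in (other.i, other.j):
            partner = other.j if other.i == c_idx else other.i
            if el[partner] == "O":
                return True
    return False


def geometric_distance_matrix(coords: Sequence[Sequence[float]] | np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distance matrix (Angstrom) of one pose."""
    xyz = np.asarray(coords, dtype=float)
    if xyz.ndim != 2 or xyz.shape[1] != 3 or xyz.shape[0] < 2:
        raise ValueError("need an (n>=2, 3) coordinate array")
    if not np.all(np.isfinite(xyz)):
        raise ValueError("coordinates must be finite")
    diff = xyz[:, None, :] - xyz[None, :, :]
    return np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
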