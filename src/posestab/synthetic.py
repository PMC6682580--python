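"""Synthetic docking-pose ensembles with a planted flexibility effect.

Real inputs for this kind of analysis come from a commercial docking
program run against receptor crystal structures.  This generator stands
in for that pipeline with the same statistical skeleton:

* compounds are branched heavy-atom chains spanning a controlled range
  of rotatable-bond counts (ideal 1.5 A bonds, tetrahedral angles,
  C/N/O decoration so charges and mass/electronegativity weights vary);
* each docked "pose" perturbs every rotatable torsion by Gaussian noise
  whose width depends on the activity class, adds small Cartesian
  jitter, and applies a random rigid motion — so pose spread grows with
  the number of rotatable bonds by construction;
* docking scores rank poses by how little their torsions were
  perturbed (plus noise), giving a meaningful top-k ordering;
* Ki/IC50 values are sampled so that activity labels round-trip through
  the labelling thresholds, including deliberately ambiguous compounds
  that exercise the exclusion path.

Everything derives from one integer seed; each compound gets its own
RNG stream keyed by (seed, compound index), so a dataset is stable
under changes of ``n_compounds``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.spatial.transform import Rotation

from .io import write_activity_csv, write_sdf_ensembles
from .model import (
    ActivityRecord,
    Atom,
    Bond,
    BondGraph,
    Molecule,
    PoseEnsemble,
    rotatable_bonds,
)

BOND_LENGTH = 1.5          # Angstrom, ideal single bond
TETRAHEDRAL = math.radians(109.47)


@dataclass
class SyntheticSpec:
    """Generator parameters; the defaults are the package's benchmark.

    Torsion noise is per activity class (radians); actives are generated
    with the larger spread so the class difference is a known planted
    effect.  The jitter and noise scales are chosen so that compound
    mean atom-position stds land in the 0.5-1.0 A range typical of
    redocking ensembles.
    """

    n_compounds: int = 200
    rotbond_range: tuple[int, int] = (1, 10)
    n_poses: int = 10
    torsion_noise_sd: dict = field(
        default_factory=lambda: {"active": 0.9, "inactive": 0.6}
    )
    coordinate_jitter_sd: float = 0.05  # Angstrom
    score_noise_sd: float = 0.2
    ambiguous_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_poses <= 10:
            raise ValueError("n_poses must be in [1, 10]")
        if any(v < 0 for v in self.torsion_noise_sd.values()):
            raise ValueError("noise standard deviations must be >= 0")
        if self.coordinate_jitter_sd < 0 or self.score_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def make_chain_molecule(n_heavy: int, n_rot: int, rng: np.random.Generator, mol_id: str = "") -> Molecule:
    """Branched heavy-atom chain with exactly ``n_rot`` rotatable bonds.

    The backbone holds n_rot + 3 atoms (an L-atom chain has L - 3
    rotatable bonds); remaining atoms are attached as terminal branches
    on internal backbone atoms, which leaves the count unchanged.
    """
    if n_rot < 0 or n_heavy < 2:
        raise ValueError("need n_rot >= 0 and n_heavy >= 2")
    if n_rot == 0:
        if n_heavy > 5:
            raise ValueError("a rotor-free molecule is limited to a 5-atom star")
        return _star_molecule(n_heavy, rng, mol_id)
    backbone = n_rot + 3
    extras = n_heavy - backbone
    if extras < 0:
        raise ValueError(f"{n_rot} rotatable bonds need at least {backbone} heavy atoms")
    if extras > 2 * (backbone - 2):
        raise ValueError("too many branch atoms for the backbone length")

    # all-trans zigzag backbone in the xy-plane
    coords = [np.zeros(3), np.array([BOND_LENGTH, 0.0, 0.0])]
    direction = 1.0
    half = math.pi - TETRAHEDRAL
    for _ in range(backbone - 2):
        step = BOND_LENGTH * np.array([math.cos(half * direction), math.sin(half * direction), 0.0])
        coords.append(coords[-1] + step)
        direction = -direction
    bonds = [Bond(i, i + 1) for i in range(backbone - 1)]

    # terminal branches at roughly tetrahedral, out-of-plane positions
    internal = list(range(1, backbone - 1))
    slots = [(i, side) for i in internal for side in (+1.0, -1.0)]
    for (host, side) in slots[:extras]:
        u_prev = _unit(coords[host - 1] - coords[host])
        u_next = _unit(coords[host + 1] - coords[host])
        bisector = -_unit(u_prev + u_next)
        normal = _unit(np.cross(u_prev, u_next))
        d = _unit(bisector + side * normal)
        idx = len(coords)
        coords.append(coords[host] + BOND_LENGTH * d)
        bonds.append(Bond(host, idx))

    elements = _decorate_elements(len(coords), rng)
    atoms = [Atom(element=e, coords=c) for e, c in zip(elements, coords)]
    return Molecule(atoms=atoms, bonds=BondGraph(bonds, len(atoms)), id=mol_id)


def _star_molecule(n_heavy: int, rng: np.random.Generator, mol_id: str) -> Molecule:
    dirs = [
        np.array([1.0, 1.0, 1.0]),
        np.array([1.0, -1.0, -1.0]),
        np.array([-1.0, 1.0, -1.0]),
        np.array([-1.0, -1.0, 1.0]),
    ]
    coords = [np.zeros(3)] + [BOND_LENGTH * _unit(d) for d in dirs[: n_heavy - 1]]
    bonds = [Bond(0, i) for i in range(1, n_heavy)]
    elements = _decorate_elements(n_heavy, rng)
    atoms = [Atom(element=e, coords=c) for e, c in zip(elements, coords)]
    return Molecule(atoms=atoms, bonds=BondGraph(bonds, n_heavy), id=mol_id)


def _decorate_elements(n: int, rng: np.random.Generator) -> list[str]:
    # carbon-rich with scattered N/O so every weighting scheme varies
    return list(rng.choice(["C", "C", "C", "N", "O"], size=n))


def _torsion_sides(molecule: Molecule) -> list[tuple[int, int, np.ndarray]]:
    """For each rotatable bond (a, b): indices of atoms on b's side,
    which rotate about the a->b axis."""
    g = molecule.bonds.to_networkx()
    sides = []
    for bond in rotatable_bonds(molecule):
        h = g.copy()
        h.remove_edge(bond.i, bond.j)
        side = np.array(sorted(nx.node_connected_component(h, bond.j)))
        sides.append((bond.i, bond.j, side))
    return sides


def sample_pose_ensemble(
    molecule: Molecule,
    spec: SyntheticSpec,
    label: str,
    rng: np.random.Generator,
) -> PoseEnsemble:
    """Draw a docking-like pose ensemble for one molecule.

    Each pose perturbs every rotatable torsion by N(0, sd^2) with the
    class-specific sd, adds isotropic coordinate jitter, then a random
    rigid motion.  The docking score is the RMS torsion perturbation
    plus noise (lower = closer to the base conformer = better).
    """
    sd = spec.torsion_noise_sd.get(label)
    if sd is None:
        sd = float(np.mean(list(spec.torsion_noise_sd.values())))
    sides = _torsion_sides(molecule)
    base = molecule.coords
    poses, scores = [], []
    for _ in range(spec.n_poses):
        xyz = base.copy()
        deltas = rng.normal(0.0, sd, size=len(sides)) if sides else np.zeros(0)
        for (a, b, side), theta in zip(sides, deltas):
            axis = _unit(xyz[b] - xyz[a])
            rot = Rotation.from_rotvec(axis * theta)
            xyz[side] = xyz[a] + rot.apply(xyz[side] - xyz[a])
        xyz += rng.normal(0.0, spec.coordinate_jitter_sd, size=xyz.shape)
        # random rigid motion: docking reports poses in the receptor frame
        quat = rng.normal(size=4)
        xyz = Rotation.from_quat(quat / np.linalg.norm(quat)).apply(xyz)
        xyz += rng.uniform(-5.0, 5.0, size=3)
        poses.append(xyz)
        quality = float(np.sqrt(np.mean(deltas**2))) if len(deltas) else 0.0
        scores.append(quality + float(rng.normal(0.0, spec.score_noise_sd)))
    return PoseEnsemble(molecule=molecule, poses=poses, docking_scores=scores)


def _compound_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(index))))


def _assign_class(index: int, spec: SyntheticSpec) -> str:
    period = max(int(round(1.0 / spec.ambiguous_fraction)), 2) if spec.ambiguous_fraction > 0 else 0
    if period and index % period == period - 1:
        return "ambiguous"
    return "active" if index % 2 == 0 else "inactive"


def _sample_affinity(cls: str, index: int, rng: np.random.Generator) -> ActivityRecord:
    if cls == "active":
        ki = 10.0 ** rng.uniform(0.0, 2.0)       # (1, 100) nM
    elif cls == "inactive":
        ki = 10.0 ** rng.uniform(3.0, 5.0)       # (1e3, 1e5) nM
    else:
        ki = rng.uniform(100.0, 1000.0)
    cid = f"CMPD_{index:04d}"
    # every fifth compound reports IC50 only (= 2 Ki), exercising that path
    if index % 5 == 2:
        return ActivityRecord(compound_id=cid, ic50_nm=2.0 * ki)
    return ActivityRecord(compound_id=cid, ki_nm=ki)


@dataclass
class BenchmarkDataset:
    ensembles: list[PoseEnsemble]
    activities: list[ActivityRecord]
    manifest: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_sdf_ensembles(self.ensembles, outdir / "poses.sdf")
        write_activity_csv(self.activities, outdir / "activity.csv")
        lines = [f"{k}={v}" for k, v in sorted(self.manifest.items())]
        (outdir / "manifest.txt").write_text("\n".join(lines) + "\n")


def make_benchmark_dataset(spec: SyntheticSpec | None = None, outdir: str | Path | None = None) -> BenchmarkDataset:
    """Generate the full synthetic benchmark: ensembles, activity records
    and a replayable manifest; optionally written as SDF + CSV."""
    spec = spec or SyntheticSpec()
    lo, hi = spec.rotbond_range
    ensembles, activities = [], []
    for i in range(spec.n_compounds):
        rng = _compound_rng(spec.seed, i)
        cls = _assign_class(i, spec)
        n_rot = int(rng.integers(lo, hi + 1))
        n_heavy = n_rot + 3 + int(rng.integers(0, 3)) if n_rot > 0 else int(rng.integers(2, 6))
        mol = make_chain_molecule(n_heavy, n_rot, rng, mol_id=f"CMPD_{i:04d}")
        record = _sample_affinity(cls, i, rng)
        ensembles.append(sample_pose_ensemble(mol, spec, record.label, rng))
        activities.append(record)
    manifest = {
        "n_compounds": spec.n_compounds,
        "rotbond_lo": lo,
        "rotbond_hi": hi,
        "n_poses": spec.n_poses,
        "torsion_noise_sd_active": spec.torsion_noise_sd["active"],
        "torsion_noise_sd_inactive": spec.torsion_noise_sd["inactive"],
        "coordinate_jitter_sd": spec.coordinate_jitter_sd,
        "score_noise_sd": spec.score_noise_sd,
        "ambiguous_fraction": spec.ambiguous_fraction,
        "seed": spec.seed,
    }
    ds = BenchmarkDataset(ensembles=ensembles, activities=activities, manifest=manifest)
    if outdir is not None:
        ds.write(outdir)
    return ds


def spec_from_manifest(path: str | Path) -> SyntheticSpec:
    """Rebuild a generator spec from a written manifest; replaying it
    reproduces the dataset byte-identically."""
    kv = {}
    for line in Path(path).read_text().splitlines():
        if line.strip():
            key, _, val = line.partition("=")
            kv[key] = val
    return SyntheticSpec(
        n_compounds=int(kv["n_compounds"]),
        rotbond_range=(int(kv["rotbond_lo"]), int(kv["rotbond_hi"])),
        n_poses=int(kv["n_poses"]),
        torsion_noise_sd={
            "active": float(kv["torsion_noise_sd_active"]),
            "inactive": float(kv["torsion_noise_sd_inactive"]),
        },
        coordinate_jitter_sd=float(kv["coordinate_jitter_sd"]),
        score_noise_sd=float(kv["score_noise_sd"]),
        ambiguous_fraction=float(kv["ambiguous_fraction"]),
        seed=int(kv["seed"]),
    )
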