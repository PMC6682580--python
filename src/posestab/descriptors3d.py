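"""Conformer-level 3D molecular descriptors.

Five families, all functions of interatomic geometry (plus per-atom
weights) and therefore invariant under rigid motion and reflection:

* 3D-MoRSE: double sums  Mor_w(s) = sum_{i<j} w_i w_j sinc(s r_ij)
  over 32 scattering parameters s = 0..31 1/Angstrom and six weighting
  schemes.  At s = 0 the sinc is identically 1 and the descriptor
  collapses to a conformation-independent constant — the anchor used to
  pin the s-index convention.
* gravitational indexes: sum m_i m_j / r_ij^2 over all or bonded pairs,
  plus square- and cube-root forms.
* principal moments of inertia and their ratios.
* geometric indexes from the distance-matrix eccentricities
  (radius, diameter, 3D Petitjean index, shape index).
* CPSA (Stanton-Jurs charged partial surface area) combining per-atom
  solvent-accessible areas with partial charges.

Undefined values (e.g. charge-weighted terms without charges) are
returned as NaN and flagged, never silently zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .charges import ensure_charges
from .elements import CARBON, UnknownElementError, element_info
from .model import BondGraph, Molecule, PoseEnsemble, geometric_distance_matrix
from .surface import DEFAULT_N_POINTS, DEFAULT_PROBE_RADIUS, SurfaceResult, shrake_rupley_sasa

N_MORSE_S = 32
WEIGHT_CODES = ("u", "m", "v", "e", "p", "c")

CPSA_CHARGE_CUTOFF = 0.2  # |q| threshold splitting "atomic" vs "polar" surface


@dataclass
class DescriptorVector:
    """Named 3D descriptor values for one conformer; NaN entries are
    undefined and carry a flag rather than a value."""

    values: dict[str, float]
    conformer_id: str = ""

    @property
    def undefined(self) -> set[str]:
        return {k for k, v in self.values.items() if not np.isfinite(v)}

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, name=self.conformer_id)


def atomic_weights(elements: Sequence[str], scheme: str, charges: np.ndarray | None = None) -> np.ndarray:
    """Per-atom weights for a MoRSE weighting scheme.

    Property weights are normalised by the carbon value (so w(C) = 1);
    the unweighted scheme is all ones and charge weights are signed and
    un-normalised.
    """
    if scheme == "u":
        return np.ones(len(elements))
    if scheme == "c":
        if charges is None:
            raise ValueError("charge weighting requested but no charges available")
        return np.asarray(charges, dtype=float)
    attr = {"m": "mass", "v": "vdw_volume", "e": "sanderson_en", "p": "polarizability"}[scheme]
    ref = getattr(CARBON, attr)
    return np.array([getattr(element_info(e), attr) for e in elements]) / ref


def morse(coords: np.ndarray, weights: np.ndarray, s_index: int) -> float:
    """3D-MoRSE descriptor at scattering parameter s = s_index - 1.

    sinc(0) = 1, so s_index = 1 yields sum_{i<j} w_i w_j regardless of
    the conformation.
    """
    if not 1 <= s_index <= N_MORSE_S:
        raise ValueError(f"s_index must be in 1..{N_MORSE_S}")
    r = geometric_distance_matrix(coords)
    iu = np.triu_indices(r.shape[0], k=1)
    s = float(s_index - 1)
    w = np.asarray(weights, dtype=float)
    wprod = w[iu[0]] * w[iu[1]]
    # np.sinc(x) = sin(pi x)/(pi x); we need sin(s r)/(s r)
    return float(np.sum(wprod * np.sinc(s * r[iu] / np.pi)))


def gravitational_indexes(coords: np.ndarray, masses: np.ndarray, bonds: BondGraph) -> dict[str, float]:
    """Gravitational indexes G = sum m_i m_j / r_ij^2 (amu^2/A^2) over all
    pairs and over bonded pairs, with square- and cube-root forms."""
    r = geometric_distance_matrix(coords)
    iu = np.triu_indices(r.shape[0], k=1)
    if np.any(r[iu] < 1e-6):
        raise ValueError("coincident atoms: degenerate geometry for gravitational index")
    m = np.asarray(masses, dtype=float)
    g_all = float(np.sum(m[iu[0]] * m[iu[1]] / r[iu] ** 2))
    g_bond = float(sum(m[b.i] * m[b.j] / r[b.i, b.j] ** 2 for b in bonds))
    return {
        "grav_all": g_all,
        "grav_all_sqrt": g_all ** 0.5,
        "grav_all_cbrt": g_all ** (1.0 / 3.0),
        "grav_bond": g_bond,
        "grav_bond_sqrt": g_bond ** 0.5,
        "grav_bond_cbrt": g_bond ** (1.0 / 3.0),
    }


def inertia_moments(coords: np.ndarray, masses: np.ndarray) -> dict[str, float]:
    """Principal moments of inertia about the centre of mass (amu A^2),
    sorted ascending, and their ratios (NaN when a denominator vanishes)."""
    xyz = np.asarray(coords, dtype=float)
    m = np.asarray(masses, dtype=float)
    com = (m[:, None] * xyz).sum(axis=0) / m.sum()
    d = xyz - com
    r2 = np.einsum("ai,ai->a", d, d)
    tensor = np.einsum("a,ij->ij", m * r2, np.eye(3)) - np.einsum("a,ai,aj->ij", m, d, d)
    eig = np.sort(np.linalg.eigvalsh(tensor))
    i1, i2, i3 = (float(v) for v in eig)
    def ratio(num: float, den: float) -> float:
        return num / den if den > 1e-10 else float("nan")
    return {
        "inertia_1": i1,
        "inertia_2": i2,
        "inertia_3": i3,
        "inertia_ratio_12": ratio(i1, i2),
        "inertia_ratio_13": ratio(i1, i3),
        "inertia_ratio_23": ratio(i2, i3),
    }


def geometric_indexes(coords: np.ndarray, shape_variant: str = "eccentricity") -> dict[str, float]:
    """Distance-matrix eccentricity descriptors.

    e_i = max_j r_ij; geometric radius R = min e_i, diameter D = max e_i,
    3D Petitjean index (D - R)/R.  ``shape_variant``: "eccentricity"
    computes the shape index as (D - R)/R, "ratio" as D/R.
    """
    if shape_variant not in {"eccentricity", "ratio"}:
        raise ValueError(f"unknown shape_variant {shape_variant!r}")
    r = geometric_distance_matrix(coords)
    ecc = r.max(axis=1)
    radius, diameter = float(ecc.min()), float(ecc.max())
    if radius < 1e-6:
        nan = float("nan")
        return {"geom_radius": radius, "geom_diameter": diameter, "petitjean_3d": nan, "shape_index_3d": nan}
    petitjean = (diameter - radius) / radius
    shape = petitjean if shape_variant == "eccentricity" else diameter / radius
    return {
        "geom_radius": radius,
        "geom_diameter": diameter,
        "petitjean_3d": petitjean,
        "shape_index_3d": shape,
    }


def canonical_coords(coords: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Rotate/reflect a conformer into a canonical shape frame.

    Axes are the eigenvectors of the coordinate covariance (ascending
    eigenvalue), each signed so that the (optionally weighted) third
    moment along it is positive, with the fifth moment as tie-break.
    Proper rotations, mirror images and translations of a conformer all
    map to the same canonical coordinates, which makes sampled
    quantities such as the accessible surface isometry-invariant by
    construction.  A moment is only trusted when it clearly exceeds the
    floating-point noise of its own absolute sum, so near-zero moments
    fall through to the next tie-break; when every odd moment vanishes
    the axis flip is a genuine shape symmetry and either sign yields
    the same geometry.  Exactly degenerate covariance eigenvalues
    (spherical/cylindrical shapes) keep an arbitrary but deterministic
    axis choice.
    """
    xyz = np.asarray(coords, dtype=float)
    w = np.ones(len(xyz)) if weights is None else np.asarray(weights, dtype=float)
    centred = xyz - xyz.mean(axis=0)
    cov = centred.T @ centred
    _, vecs = np.linalg.eigh(cov)
    proj = centred @ vecs
    for axis in range(3):
        y = proj[:, axis]
        sign = 1.0
        for power in (3, 5):
            moment = float(np.sum(w * y**power))
            scale = float(np.sum(w * np.abs(y) ** power))
            if abs(moment) > 1e-9 * scale:
                sign = np.sign(moment)
                break
        if sign < 0:
            proj[:, axis] *= -1.0
    return proj


_CPSA_NAMES = (
    ["ppsa1", "ppsa2", "ppsa3", "pnsa1", "pnsa2", "pnsa3"]
    + ["dpsa1", "dpsa2", "dpsa3"]
    + ["fpsa1", "fpsa2", "fpsa3", "fnsa1", "fnsa2", "fnsa3"]
    + ["wpsa1", "wpsa2", "wpsa3", "wnsa1", "wnsa2", "wnsa3"]
    + ["rpcg", "rncg", "rpcs", "rncs"]
    + ["tasa", "tpsa_surf", "rasa", "rpsa"]
)


def cpsa(charges: np.ndarray, surface: SurfaceResult) -> dict[str, float]:
    """Stanton-Jurs charged partial surface area descriptors.

    Surface-sum descriptors over an empty charge class are 0 (an empty
    sum); relative-charge descriptors (RPCG/RNCG/RPCS/RNCS), which
    divide by the class total charge, are NaN when the class is empty.
    """
    q = np.asarray(charges, dtype=float)
    sa = surface.atom_areas
    tsa = surface.total_area
    pos, neg = q > 0, q < 0
    nan = float("nan")

    ppsa1 = float(sa[pos].sum())
    pnsa1 = float(sa[neg].sum())
    qtot_pos = float(q[pos].sum())
    qtot_neg = float(q[neg].sum())  # negative number
    ppsa2 = qtot_pos * ppsa1
    pnsa2 = qtot_neg * pnsa1
    ppsa3 = float((q[pos] * sa[pos]).sum())
    pnsa3 = float((q[neg] * sa[neg]).sum())

    out: dict[str, float] = {
        "ppsa1": ppsa1, "ppsa2": ppsa2, "ppsa3": ppsa3,
        "pnsa1": pnsa1, "pnsa2": pnsa2, "pnsa3": pnsa3,
    }
    for k in (1, 2, 3):
        out[f"dpsa{k}"] = out[f"ppsa{k}"] - out[f"pnsa{k}"]
    for k in (1, 2, 3):
        out[f"fpsa{k}"] = out[f"ppsa{k}"] / tsa if tsa > 0 else nan
        out[f"fnsa{k}"] = out[f"pnsa{k}"] / tsa if tsa > 0 else nan
    for k in (1, 2, 3):
        out[f"wpsa{k}"] = out[f"ppsa{k}"] * tsa / 1000.0
        out[f"wnsa{k}"] = out[f"pnsa{k}"] * tsa / 1000.0
    if pos.any():
        qmax = float(q[pos].max())
        out["rpcg"] = qmax / qtot_pos
        out["rpcs"] = float(sa[np.flatnonzero(pos)[np.argmax(q[pos])]]) * out["rpcg"]
    else:
        out["rpcg"] = out["rpcs"] = nan
    if neg.any():
        qmin = float(q[neg].min())
        out["rncg"] = qmin / qtot_neg  # both negative -> positive fraction
        out["rncs"] = float(sa[np.flatnonzero(neg)[np.argmin(q[neg])]]) * out["rncg"]
    else:
        out["rncg"] = out["rncs"] = nan
    polar = np.abs(q) >= CPSA_CHARGE_CUTOFF
    out["tasa"] = float(sa[~polar].sum())
    out["tpsa_surf"] = float(sa[polar].sum())
    out["rasa"] = out["tasa"] / tsa if tsa > 0 else nan
    out["rpsa"] = out["tpsa_surf"] / tsa if tsa > 0 else nan
    return out


@dataclass
class ComputeConfig:
    """Knobs for descriptor computation.

    probe_radius (A) and sasa_points control the accessible-surface
    model; charge_source selects input-supplied vs Gasteiger charges;
    shape_variant picks the geometric shape-index definition.
    """

    probe_radius: float = DEFAULT_PROBE_RADIUS
    sasa_points: int = DEFAULT_N_POINTS
    charge_source: str = "input"
    shape_variant: str = "eccentricity"


def descriptor_names() -> list[str]:
    """Stable, documented descriptor ordering used in every output table."""
    names = [f"morse_{w}_{s}" for w in WEIGHT_CODES for s in range(1, N_MORSE_S + 1)]
    names += ["grav_all", "grav_all_sqrt", "grav_all_cbrt", "grav_bond", "grav_bond_sqrt", "grav_bond_cbrt"]
    names += ["inertia_1", "inertia_2", "inertia_3", "inertia_ratio_12", "inertia_ratio_13", "inertia_ratio_23"]
    names += ["geom_radius", "geom_diameter", "petitjean_3d", "shape_index_3d"]
    names += _CPSA_NAMES
    return names


def compute_descriptor_vector(
    molecule: Molecule,
    coords: np.ndarray | None = None,
    config: ComputeConfig | None = None,
    charges: np.ndarray | None = None,
    conformer_id: str = "",
) -> DescriptorVector:
    """All descriptor families for one conformer, in the stable order.

    Never raises for definable inputs: descriptors whose prerequisites
    are unavailable (e.g. charges for an unparameterised element) come
    back NaN-flagged.
    """
    config = config or ComputeConfig()
    xyz = molecule.coords if coords is None else np.asarray(coords, dtype=float)
    elements = molecule.elements
    masses = molecule.masses
    if charges is None:
        try:
            charges = ensure_charges(molecule, source=config.charge_source)
        except (UnknownElementError, ValueError):
            charges = None

    values: dict[str, float] = {}
    r = geometric_distance_matrix(xyz)
    iu = np.triu_indices(len(elements), k=1)
    s_grid = np.arange(N_MORSE_S, dtype=float)  # s = s_index - 1
    sinc = np.sinc(s_grid[:, None] * r[iu][None, :] / np.pi)
    for w in WEIGHT_CODES:
        if w == "c" and charges is None:
            for s_index in range(1, N_MORSE_S + 1):
                values[f"morse_{w}_{s_index}"] = float("nan")
            continue
        wt = atomic_weights(elements, w, charges)
        wprod = wt[iu[0]] * wt[iu[1]]
        mors = sinc @ wprod
        for s_index in range(1, N_MORSE_S + 1):
            values[f"morse_{w}_{s_index}"] = float(mors[s_index - 1])

    values.update(gravitational_indexes(xyz, masses, molecule.bonds))
    values.update(inertia_moments(xyz, masses))
    values.update(geometric_indexes(xyz, shape_variant=config.shape_variant))

    # SASA is sampled in the canonical shape frame so the CPSA family is
    # rigid-motion and mirror invariant like every analytic descriptor
    surface = shrake_rupley_sasa(
        canonical_coords(xyz, weights=masses), elements, config.probe_radius, config.sasa_points
    )
    if charges is None:
        values.update({name: float("nan") for name in _CPSA_NAMES})
    else:
        values.update(cpsa(charges, surface))
    return DescriptorVector(values={n: values[n] for n in descriptor_names()}, conformer_id=conformer_id)


def descriptor_table(ensembles: Sequence[PoseEnsemble], config: ComputeConfig | None = None) -> pd.DataFrame:
    """One row per (compound, pose): id columns, docking score, then all
    descriptors in the stable order.  Pose ranks follow file order."""
    config = config or ComputeConfig()
    rows = []
    for ens in ensembles:
        mol = ens.molecule
        try:
            charges = ensure_charges(mol, source=config.charge_source)
        except (UnknownElementError, ValueError):
            charges = None
        for rank, (xyz, score) in enumerate(zip(ens.poses, ens.docking_scores)):
            vec = compute_descriptor_vector(
                mol, xyz, config, charges=charges, conformer_id=f"{mol.id}#{rank}"
            )
            row = {"compound_id": mol.id, "pose_rank": rank, "docking_score": score}
            row.update(vec.values)
            rows.append(row)
    cols = ["compound_id", "pose_rank", "docking_score"] + descriptor_names()
    return pd.DataFrame(rows, columns=cols)


def write_descriptor_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.10g")
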