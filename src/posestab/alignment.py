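"""Kabsch superposition and atom-position variability across poses.

The pose-consistency statistic on the geometry side: all top-k poses of
a compound are rigidly superposed onto the best-scoring pose (heavy
atoms only — docking programs place hydrogens variably) and the
root-mean-square fluctuation of each atom about its mean aligned
position is taken; the compound-level value is the mean RMSF over heavy
atoms.  The statistic is invariant to arbitrary rigid pre-motions of
individual poses because superposition removes them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import PoseEnsemble


@dataclass
class Superposition:
    rotation: np.ndarray     # 3x3 proper rotation, det = +1
    translation: np.ndarray  # 3-vector, Angstrom
    rmsd: float              # over masked atoms, after superposition

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class AtomVariability:
    rmsf: np.ndarray          # per-atom positional std about the mean, Angstrom
    heavy_mask: np.ndarray
    n_poses: int

    @property
    def compound_mean(self) -> float:
        return float(self.rmsf[self.heavy_mask].mean())


def kabsch(moving: np.ndarray, reference: np.ndarray, mask: np.ndarray | None = None) -> Superposition:
    """Least-squares optimal rigid superposition of ``moving`` onto
    ``reference`` over masked atoms (SVD solution, reflection corrected).

    Requires >= 3 non-collinear masked atoms for a unique rotation.
    """
    mov = np.asarray(moving, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mov.shape != ref.shape:
        raise ValueError("coordinate sets must have equal shapes")
    if mask is None:
        mask = np.ones(len(mov), dtype=bool)
    m, r = mov[mask], ref[mask]
    if len(m) < 3:
        raise ValueError("need at least 3 masked atoms for a unique rotation")
    mc, rc = m.mean(axis=0), r.mean(axis=0)
    m0, r0 = m - mc, r - rc
    # collinearity check: rank of the centred point cloud
    if np.linalg.matrix_rank(m0, tol=1e-8) < 2 or np.linalg.matrix_rank(r0, tol=1e-8) < 2:
        raise ValueError("masked atoms are collinear: rotation is degenerate")
    h = m0.T @ r0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = rc - rot @ mc
    aligned = m @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((aligned - r) ** 2, axis=1))))
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd)


def ensemble_atom_std(ensemble: PoseEnsemble, k: int | None = None, ddof: int = 0) -> AtomVariability:
    """Per-atom RMSF over the top-k poses after superposition.

    Poses are ranked by docking score (lowest best, ties by file order),
    the best pose is the alignment reference, and
    rmsf_a = sqrt( mean_p ||x_{p,a} - mu_a||^2 ) with mu_a the mean
    aligned position (``ddof=1`` switches to the sample form).  Needs at
    least 2 selected poses.
    """
    order = np.argsort(ensemble.docking_scores, kind="stable")
    if k is not None:
        order = order[:k]
    if len(order) < 2:
        raise ValueError("atom variability needs at least 2 poses")
    heavy = ensemble.molecule.heavy_mask()
    ref = ensemble.poses[order[0]]
    aligned = [ref]
    for idx in order[1:]:
        sup = kabsch(ensemble.poses[idx], ref, mask=heavy)
        aligned.append(sup.apply(ensemble.poses[idx]))
    stack = np.stack(aligned)  # (k, n_atoms, 3)
    mu = stack.mean(axis=0)
    dev2 = np.sum((stack - mu) ** 2, axis=2)  # squared 3D deviation
    n = len(order)
    rmsf = np.sqrt(dev2.sum(axis=0) / (n - ddof))
    return AtomVariability(rmsf=rmsf, heavy_mask=heavy, n_poses=n)
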