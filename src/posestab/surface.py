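"""Shrake-Rupley solvent-accessible surface area.

Each atom is inflated by the probe radius and sampled with a
deterministic Fibonacci-spiral point set; a sample point is accessible
iff it lies outside every other inflated sphere.  The spiral (no RNG)
makes areas bit-stable across runs, and the point set rides with the
molecule, so areas are rigid-motion invariant to numerical precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .elements import element_info

DEFAULT_PROBE_RADIUS = 1.4  # Angstrom, water probe
DEFAULT_N_POINTS = 960


@dataclass
class SurfaceResult:
    atom_areas: np.ndarray  # Angstrom^2, one per atom
    probe_radius: float
    n_points: int

    @property
    def total_area(self) -> float:
        return float(self.atom_areas.sum())


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (Fibonacci spiral)."""
    k = np.arange(n, dtype=float)
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = 2.0 * math.pi * k / phi
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def shrake_rupley_sasa(
    coords: Sequence[Sequence[float]] | np.ndarray,
    elements: Sequence[str],
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> SurfaceResult:
    """Per-atom solvent-accessible area at ``r_vdw + probe_radius``.

    ``n_points`` >= 96 sample points per atom; the per-atom area is the
    exposed point fraction times the full inflated-sphere area.
    """
    if n_points < 96:
        raise ValueError("n_points must be >= 96 for a usable area estimate")
    if probe_radius < 0:
        raise ValueError("probe_radius must be >= 0")
    xyz = np.asarray(coords, dtype=float)
    radii = np.array([element_info(e).vdw_radius for e in elements]) + probe_radius
    n_atoms = xyz.shape[0]
    unit = sphere_points(n_points)
    areas = np.empty(n_atoms)
    for i in range(n_atoms):
        pts = xyz[i] + radii[i] * unit
        exposed = np.ones(n_points, dtype=bool)
        # only neighbours whose inflated sphere can reach atom i's surface
        d = np.linalg.norm(xyz - xyz[i], axis=1)
        near = np.where((d < radii + radii[i]) & (np.arange(n_atoms) != i))[0]
        for j in near:
            exposed &= np.linalg.norm(pts - xyz[j], axis=1) >= radii[j]
            if not exposed.any():
                break
        areas[i] = exposed.mean() * 4.0 * math.pi * radii[i] ** 2
    return SurfaceResult(atom_areas=areas, probe_radius=probe_radius, n_points=n_points)
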