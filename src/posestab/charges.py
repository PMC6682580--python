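"""Gasteiger-Marsili partial charges (PEOE).

Partial equalisation of orbital electronegativities: each atom's
electronegativity is a quadratic in its current charge,
chi(q) = a + b q + c q^2, and in every iteration charge flows across
each bond from the less to the more electronegative atom, damped by
(1/2)^n at iteration n.  Charges converge geometrically and conserve
the molecule's formal charge exactly (transfers are antisymmetric).

Charges read from input files take precedence over this model: the
pipeline only calls it for atoms that arrived without charges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .elements import UnknownElementError, chi_plus, gasteiger_params
from .model import Molecule

DEFAULT_ITERATIONS = 8


@dataclass
class ChargeResult:
    charges: np.ndarray  # elementary-charge units, one per atom
    iterations_run: int


def gasteiger_charges(
    molecule: Molecule,
    n_iterations: int = DEFAULT_ITERATIONS,
    formal_charge: float = 0.0,
) -> ChargeResult:
    """PEOE charges for a molecule; deterministic, order-independent.

    Raises :class:`UnknownElementError` listing the offending atoms when
    the parameter table does not cover an element present.
    """
    elements = molecule.elements
    hybrid = molecule.hybridisations()
    bad = []
    params, plus = [], []
    for idx, (el, hyb) in enumerate(zip(elements, hybrid)):
        try:
            params.append(gasteiger_params(el, hyb))
            plus.append(chi_plus(el, hyb))
        except UnknownElementError:
            bad.append(f"{el}{idx}")
    if bad:
        raise UnknownElementError(
            f"no Gasteiger parameters for atoms {bad}; supply precomputed charges"
        )
    a = np.array([p[0] for p in params])
    b = np.array([p[1] for p in params])
    c = np.array([p[2] for p in params])
    plus_arr = np.array(plus)

    n = molecule.n_atoms
    q = np.full(n, formal_charge / n)  # spread any net charge uniformly
    edges = [(bond.i, bond.j) for bond in molecule.bonds]
    damping = 1.0
    for _ in range(n_iterations):
        damping *= 0.5
        chi = a + b * q + c * q * q
        dq = np.zeros(n)
        for i, j in edges:
            if chi[j] > chi[i]:
                transfer = (chi[j] - chi[i]) / plus_arr[i] * damping
                dq[i] += transfer
                dq[j] -= transfer
            else:
                transfer = (chi[i] - chi[j]) / plus_arr[j] * damping
                dq[j] += transfer
                dq[i] -= transfer
        q = q + dq
    return ChargeResult(charges=q, iterations_run=n_iterations)


def ensure_charges(molecule: Molecule, source: str = "input") -> np.ndarray:
    """Return per-atom charges, preferring input-supplied values.

    ``source``: "input" uses charges carried by the atoms and falls back
    to Gasteiger when absent; "gasteiger" always recomputes.
    """
    if source not in {"input", "gasteiger"}:
        raise ValueError(f"unknown charge source {source!r}")
    if source == "input":
        existing = molecule.charges
        if existing is not None:
            return existing
    return gasteiger_charges(molecule).charges
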