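"""Frozen per-element property table.

All descriptor weighting constants used by the package live here so that
results are reproducible across environments and library versions.  The
element set covers the chemistry of typical aminergic-GPCR ligands
(H, C, N, O plus S, P and halogens); anything else is rejected loudly.

Sources (values frozen at package creation):
  mass                 standard atomic weights (IUPAC 2021, rounded)
  vdw_radius           Bondi van der Waals radii, Angstrom
  sanderson_en         Sanderson electronegativities (Dragon convention)
  polarizability       atomic dipole polarizabilities, Angstrom^3
  vdw_volume           sphere volume of the Bondi radius, Angstrom^3
  gasteiger            PEOE a, b, c coefficients per hybridisation class
                       (Gasteiger & Marsili electronegativity polynomial
                       chi(q) = a + b q + c q^2)
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class ElementInfo:
    symbol: str
    mass: float            # amu
    vdw_radius: float      # Angstrom
    sanderson_en: float
    polarizability: float  # Angstrom^3
    vdw_volume: float      # Angstrom^3


def _vol(r: float) -> float:
    return 4.0 / 3.0 * math.pi * r**3


_ELEMENTS = {
    e.symbol: e
    for e in [
        ElementInfo("H", 1.008, 1.20, 2.592, 0.667, _vol(1.20)),
        ElementInfo("C", 12.011, 1.70, 2.746, 1.760, _vol(1.70)),
        ElementInfo("N", 14.007, 1.55, 3.194, 1.100, _vol(1.55)),
        ElementInfo("O", 15.999, 1.52, 3.654, 0.802, _vol(1.52)),
        ElementInfo("F", 18.998, 1.47, 4.000, 0.557, _vol(1.47)),
        ElementInfo("P", 30.974, 1.80, 2.515, 3.630, _vol(1.80)),
        ElementInfo("S", 32.06, 1.80, 2.957, 2.900, _vol(1.80)),
        ElementInfo("Cl", 35.45, 1.75, 3.475, 2.180, _vol(1.75)),
        ElementInfo("Br", 79.904, 1.85, 3.219, 3.050, _vol(1.85)),
        ElementInfo("I", 126.904, 1.98, 2.778, 5.350, _vol(1.98)),
    ]
}

# PEOE coefficients (a, b, c) keyed by (element, hybridisation).
# Hybridisation is "sp3" / "sp2" / "sp"; halogens and hydrogen have a
# single class.  chi_plus (cation electronegativity, the damping
# denominator) is a + b + c except for hydrogen where the original
# parameterisation fixes 20.02.
_GASTEIGER = {
    ("H", "sp3"): (7.17, 6.24, -0.56),
    ("C", "sp3"): (7.98, 9.18, 1.88),
    ("C", "sp2"): (8.79, 9.32, 1.51),
    ("C", "sp"): (10.39, 9.45, 0.73),
    ("N", "sp3"): (11.54, 10.82, 1.36),
    ("N", "sp2"): (12.87, 11.15, 0.85),
    ("N", "sp"): (15.68, 11.70, -0.27),
    ("O", "sp3"): (14.18, 12.92, 1.39),
    ("O", "sp2"): (17.07, 13.79, 0.47),
    ("F", "sp3"): (14.66, 13.85, 2.31),
    ("Cl", "sp3"): (11.00, 9.69, 1.35),
    ("Br", "sp3"): (10.08, 8.47, 1.16),
    ("I", "sp3"): (9.90, 7.96, 0.96),
    ("S", "sp3"): (10.14, 9.13, 1.38),
    ("P", "sp3"): (8.90, 8.24, 0.96),
}

H_CHI_PLUS = 20.02

SUPPORTED_ELEMENTS = frozenset(_ELEMENTS)

# carbon values used to normalise weighting schemes (Dragon convention)
CARBON = _ELEMENTS["C"]


class UnknownElementError(KeyError):
    """Raised when a property is requested for an element not in the table."""


def element_info(symbol: str) -> ElementInfo:
    try:
        return _ELEMENTS[symbol]
    except KeyError:
        raise UnknownElementError(
            f"element {symbol!r} is not in the property table "
            f"(supported: {sorted(_ELEMENTS)})"
        ) from None


def gasteiger_params(symbol: str, hybridisation: str) -> tuple[float, float, float]:
    """PEOE (a, b, c) for an element/hybridisation class.

    Falls back to the sp3 class when the specific hybridisation is not
    parameterised (halogens, S, P).
    """
    key = (symbol, hybridisation)
    if key in _GASTEIGER:
        return _GASTEIGER[key]
    key = (symbol, "sp3")
    if key in _GASTEIGER:
        return _GASTEIGER[key]
    raise UnknownElementError(
        f"no Gasteiger parameters for element {symbol!r}; supply precomputed "
        "partial charges instead"
    )


def chi_plus(symbol: str, hybridisation: str) -> float:
    if symbol == "H":
        return H_CHI_PLUS
    a, b, c = gasteiger_params(symbol, hybridisation)
    return a + b + c
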