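"""Parametric photon attenuation coefficients for the phantom/beam toy model.

Each entry maps a material name to a linear attenuation coefficient function
``mu(E_keV) -> 1/mm``.  The parameterization is a deliberately simple two-term
form,

    mu(E) = pe100 * (100/E)**3  +  c100 * (100/E)**0.40,

a photoelectric-like E^-3 term plus a slowly declining Compton-like term, with
the two constants set to the material's approximate linear attenuation at
100 keV and ~2 MeV.  It is adequate for ordering beams and materials over
25 keV – 6 MeV; it is not dosimetric data.

Polystyrene is the exception: its photon attenuation is modelled as a constant
(energy-independent, Compton-dominated) value.  The electron-filter sweep is
meant to remove electrons while leaving the low-energy photon share of the
beam essentially untouched, which an energy-flat coefficient makes exact.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

MuFunction = Callable[[np.ndarray], np.ndarray]


def _two_term(pe100: float, c100: float, compton_exp: float = 0.40) -> MuFunction:
    def mu(energy_kev):
        e = np.asarray(energy_kev, dtype=float)
        return pe100 * (100.0 / e) ** 3 + c100 * (100.0 / e) ** compton_exp

    return mu


def _constant(value: float) -> MuFunction:
    def mu(energy_kev):
        return np.full_like(np.asarray(energy_kev, dtype=float), value)

    return mu


#: linear attenuation functions, 1/mm, indexed by material name
MATERIALS: dict[str, MuFunction] = {
    "aluminum": _two_term(0.0055, 0.0405),
    "brass": _two_term(0.285, 0.125),
    "acrylic": _two_term(0.0017, 0.0178),
    "water": _two_term(0.0020, 0.0168),
    "polystyrene": _constant(0.0105),
}


def material_mu(name: str) -> MuFunction:
    """Return the attenuation function for *name* (KeyError lists options)."""
    try:
        return MATERIALS[name]
    except KeyError:
        raise KeyError(
            f"unknown material {name!r}; known: {sorted(MATERIALS)}"
        ) from None
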