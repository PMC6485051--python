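"""Toy model of the imaging beams and the polystyrene electron filter.

Two beam qualities are modelled:

``al_target``
    The low-Z (aluminum) target beam: a thin-target bremsstrahlung-like
    1/E-weighted spectrum with a low-energy absorption rolloff, concentrating
    roughly a third of the photon fluence in the diagnostic 25–150 keV window.
``6mv``
    A hardened megavoltage therapy beam with negligible fluence below
    150 keV.

The spectra are stand-ins for Monte Carlo-scored fluence: only their energy
*ordering* and window fractions matter downstream (image contrast, detector
blur).  The electron filter model is likewise parametric: Beer–Lambert photon
transmission plus a smooth electron survival curve that reaches ~zero at the
CSDA range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigError, DomainError, UndefinedSpectrumError
from .materials import MuFunction, material_mu

#: diagnostic-energy photon window (keV)
LOW_ENERGY_WINDOW = (25.0, 150.0)

#: unfiltered particle yields of the aluminum-target beam, per incident history
AL_TARGET_PHOTON_YIELD = 0.642
AL_TARGET_ELECTRON_YIELD = 0.358

#: default spectrum-shape parameters, one set per beam mode
DEFAULT_SPECTRUM_PARAMS = {
    "al_target": {"max_energy_kev": 6000.0, "rolloff_kev": 28.0},
    "6mv": {"max_energy_kev": 6000.0, "peak_scale_kev": 700.0},
}


@dataclass(frozen=True)
class BeamSpectrum:
    """Binned photon-energy fluence.

    bin_edges are in keV and strictly increasing; weights are relative
    fluence per bin (dimensionless, non-negative, at least one positive).
    """

    bin_edges: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if edges.ndim != 1 or w.ndim != 1 or len(w) != len(edges) - 1:
            raise DomainError("need len(weights) == len(bin_edges) - 1")
        if not np.all(np.diff(edges) > 0):
            raise DomainError("bin_edges must be strictly increasing")
        if np.any(w < 0):
            raise DomainError("weights must be non-negative")
        if not np.any(w > 0):
            raise DomainError("at least one weight must be positive")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "weights", w)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())


@dataclass(frozen=True)
class ParticleMix:
    """Particle bookkeeping at the scoring plane below the filter.

    ``photon_fraction`` and ``electron_fraction`` are per incident history.
    ``low_energy_photon_fraction`` is the 25–150 keV share *among transmitted
    photons* — the quantity that stays nearly constant as the filter thickens
    while the electron fraction collapses.
    """

    photon_fraction: float
    electron_fraction: float
    low_energy_photon_fraction: float

    def __post_init__(self):
        for name in ("photon_fraction", "electron_fraction", "low_energy_photon_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DomainError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class FilterSpec:
    """Electron-filter slab: material, thickness and effective electron range."""

    material: str
    thickness_mm: float
    csda_range_mm: float
    mu_of_E: MuFunction | None = None

    def __post_init__(self):
        if self.thickness_mm < 0:
            raise DomainError("filter thickness must be >= 0")
        if self.csda_range_mm <= 0:
            raise DomainError("csda_range must be > 0")
        if self.mu_of_E is None:
            object.__setattr__(self, "mu_of_E", material_mu(self.material))


def default_polystyrene_filter(thickness_mm: float = 20.0) -> FilterSpec:
    """20 mm polystyrene slab with a 20 mm effective electron range."""
    return FilterSpec(material="polystyrene", thickness_mm=thickness_mm,
                      csda_range_mm=20.0)


def make_toy_spectrum(mode: str, params: dict | None = None) -> BeamSpectrum:
    """Build the default parametric spectrum for a beam mode.

    The energy grid is 1 keV bins from 1 keV to the nominal maximum, so the
    25/150 keV window boundaries fall exactly on bin edges.
    """
    if mode not in DEFAULT_SPECTRUM_PARAMS:
        raise ConfigError(f"unknown beam mode {mode!r}; expected 'al_target' or '6mv'")
    p = dict(DEFAULT_SPECTRUM_PARAMS[mode])
    if params:
        p.update(params)
    emax = float(p["max_energy_kev"])
    edges = np.arange(1.0, emax + 1.0)
    e = 0.5 * (edges[:-1] + edges[1:])
    if mode == "al_target":
        # Kramers thin-target shape with a low-energy self-absorption rolloff
        w = (emax - e) / e * np.exp(-(p["rolloff_kev"] / e) ** 3)
    else:
        e0 = float(p["peak_scale_kev"])
        w = (e / e0) ** 2 * np.exp(-e / e0)
    return BeamSpectrum(edges, w)


def low_energy_fraction(spec: BeamSpectrum,
                        lo: float = LOW_ENERGY_WINDOW[0],
                        hi: float = LOW_ENERGY_WINDOW[1]) -> float:
    """Fraction of fluence in the [lo, hi] keV window.

    Bins straddling a boundary contribute pro-rata by their overlap with the
    window (fluence assumed uniform within a bin).
    """
    if not lo < hi:
        raise DomainError(f"need lo < hi, got [{lo}, {hi}]")
    total = spec.total_weight
    if total <= 0:
        raise UndefinedSpectrumError("spectrum has zero total weight")
    left = spec.bin_edges[:-1]
    right = spec.bin_edges[1:]
    overlap = np.clip(np.minimum(hi, right) - np.maximum(lo, left), 0.0, None)
    frac = overlap / (right - left)
    return float((spec.weights * frac).sum() / total)


def electron_survival(filt: FilterSpec, thickness_mm: float) -> float:
    """Surviving electron fraction after *thickness_mm* of filter material.

    Model: exp(-5 (t/R)^2) with R the CSDA range — a smooth monotone falloff
    reaching e^-5 < 0.01 at R.  A model choice, not a physics claim.
    """
    if thickness_mm < 0:
        raise DomainError("thickness must be >= 0")
    return float(np.exp(-5.0 * (thickness_mm / filt.csda_range_mm) ** 2))


def apply_filter(spec: BeamSpectrum, filt: FilterSpec) -> BeamSpectrum:
    """Beer–Lambert photon transmission through the filter (no buildup)."""
    mu = np.asarray(filt.mu_of_E(spec.bin_centers), dtype=float)
    return BeamSpectrum(spec.bin_edges, spec.weights * np.exp(-mu * filt.thickness_mm))


def effective_mu(spec: BeamSpectrum, mu_of_E: MuFunction) -> float:
    """Spectrum-weighted mean linear attenuation coefficient, 1/mm."""
    mu = np.asarray(mu_of_E(spec.bin_centers), dtype=float)
    return float((spec.weights * mu).sum() / spec.total_weight)


def filter_sweep(spec: BeamSpectrum,
                 filt: FilterSpec,
                 thicknesses_mm: Sequence[float],
                 photon_yield: float = AL_TARGET_PHOTON_YIELD,
                 electron_yield: float = AL_TARGET_ELECTRON_YIELD,
                 ) -> list[ParticleMix]:
    """Particle mix at the scoring plane for each filter thickness.

    ``photon_yield`` / ``electron_yield`` are the unfiltered per-history
    yields of the target (defaults: the aluminum-target beam).  Thicknesses
    must be sorted ascending.
    """
    ts = list(thicknesses_mm)
    if not ts:
        raise DomainError("thickness list must be non-empty")
    if any(b < a for a, b in zip(ts, ts[1:])):
        raise DomainError("thicknesses must be sorted ascending")
    out = []
    for t in ts:
        filtered = apply_filter(spec, replace(filt, thickness_mm=t))
        out.append(ParticleMix(
            photon_fraction=photon_yield * filtered.total_weight / spec.total_weight,
            electron_fraction=electron_yield * electron_survival(filt, t),
            low_energy_photon_fraction=low_energy_fraction(filtered),
        ))
    return out
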