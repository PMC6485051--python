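"""Synthetic-data generator: portal images of the phantom and dose-curve pairs.

This module stands in for measured computed-radiography images and
water-phantom scans.  The renderer projects the phantom through the imaging
geometry, attenuates the beam with a monoenergetic-equivalent effective
coefficient per material (the spectrum-weighted mean μ̄ of the beam, so image
contrast follows 1 − exp(−Δμ̄·t) exactly), blurs with a beam-quality-dependent
Gaussian point-spread function, adds scaled-Poisson plus Gaussian read noise,
and quantizes to 16 bits.

The energy dependence of the real detector is folded into the per-mode PSF
width and gain rather than an absorbed-energy model: the softer aluminum
target beam gets a narrower PSF and sees larger attenuation differences, which
is the level of mechanism the downstream analyses can test.

Images are produced non-inverted (dark = high attenuation happens to *low*
signal here since signal tracks transmission); display inversion is a view
flag only and is never applied before analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage

from .beam_model import BeamSpectrum, effective_mu, make_toy_spectrum
from .errors import DomainError, GeometryError
from .gamma_analysis import DoseProfile1D
from .materials import material_mu
from .phantom_model import ImagingGeometry, PhantomSpec, magnification

#: native computed-radiography plate grid (rows, cols) and pixel pitch
CR_CANVAS = (2320, 2828)
CR_PIXEL_SPACING_MM = 0.15

#: default imager-plane PSF width per beam mode, mm
DEFAULT_PSF_SIGMA_MM = {"al_target": 0.3, "6mv": 0.5}


@dataclass(frozen=True)
class DetectorModel:
    """Imaging chain parameters: sampling, blur, gain and noise."""

    psf_sigma_mm: float
    gain: float = 30000.0
    poisson_scale: float = 4.0
    gaussian_sigma: float = 30.0
    bit_depth: int = 16
    pixel_spacing_mm: float = CR_PIXEL_SPACING_MM
    canvas_shape: tuple[int, int] | Literal["phantom"] = "phantom"

    def __post_init__(self):
        if self.psf_sigma_mm < 0:
            raise DomainError("psf_sigma must be >= 0")
        if self.gain <= 0:
            raise DomainError("gain must be positive")
        if self.poisson_scale < 0 or self.gaussian_sigma < 0:
            raise DomainError("noise parameters must be >= 0")
        if self.pixel_spacing_mm <= 0:
            raise DomainError("pixel spacing must be positive")


@dataclass(frozen=True)
class PortalImage:
    """2-D grayscale portal image plus acquisition metadata."""

    pixels: np.ndarray
    pixel_spacing_mm: float
    beam_mode: str
    inverted: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise DomainError("pixels must be a non-empty 2-D array")
        if self.pixel_spacing_mm <= 0:
            raise DomainError("pixel spacing must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def default_detector(mode: str, scale: float = 1.0,
                     canvas: Literal["cr", "phantom"] = "phantom",
                     noise: bool = True, psf_sigma_mm: float | None = None,
                     ) -> DetectorModel:
    """Detector defaults for a beam mode, optionally downscaled.

    ``scale`` < 1 coarsens the pixel pitch and shrinks the canvas by the same
    factor (desk-scale runs); ``canvas="phantom"`` sizes the canvas to the
    phantom footprint instead of the full plate.
    """
    if not 0 < scale <= 1:
        raise DomainError("scale must lie in (0, 1]")
    if psf_sigma_mm is None:
        psf_sigma_mm = DEFAULT_PSF_SIGMA_MM.get(mode, 0.4)
    shape: tuple[int, int] | Literal["phantom"]
    if canvas == "cr":
        shape = (int(CR_CANVAS[0] * scale), int(CR_CANVAS[1] * scale))
    else:
        shape = "phantom"
    return DetectorModel(
        psf_sigma_mm=psf_sigma_mm,
        poisson_scale=4.0 if noise else 0.0,
        gaussian_sigma=30.0 if noise else 0.0,
        pixel_spacing_mm=CR_PIXEL_SPACING_MM / scale,
        canvas_shape=shape,
    )


def _canvas_shape(phantom: PhantomSpec, geom: ImagingGeometry,
                  det: DetectorModel, margin_mm: float = 12.0) -> tuple[int, int]:
    if det.canvas_shape != "phantom":
        return det.canvas_shape  # type: ignore[return-value]
    m = magnification(geom)
    x0, x1, y0, y1 = phantom.bbox()
    half_w = (max(abs(x0), abs(x1)) * m + margin_mm)
    half_h = (max(abs(y0), abs(y1)) * m + margin_mm)
    cols = 2 * int(math.ceil(half_w / det.pixel_spacing_mm)) + 1
    rows = 2 * int(math.ceil(half_h / det.pixel_spacing_mm)) + 1
    return rows, cols


def _optical_depth(phantom: PhantomSpec, mu_eff: dict[str, float],
                   x_mm: np.ndarray, y_mm: np.ndarray) -> np.ndarray:
    """Line-integral μ̄·t map over a phantom-plane grid (x along cols)."""
    tau = np.full((len(y_mm), len(x_mm)),
                  mu_eff["base"] * phantom.base_thickness_mm)
    X = x_mm[None, :]
    Y = y_mm[:, None]
    # bars occupy alternate half-periods, measured from the block start
    for b in phantom.lamella_blocks:
        th = math.radians(b.orientation_deg)
        u = (X - b.center[0]) * math.cos(th) + (Y - b.center[1]) * math.sin(th)
        v = -(X - b.center[0]) * math.sin(th) + (Y - b.center[1]) * math.cos(th)
        half = b.pattern_length_mm / 2.0
        inside = (np.abs(v) <= b.bar_length_mm / 2.0) & (u >= -half) & (u < half)
        bar = np.floor((u + half) / b.width_mm).astype(int) % 2 == 0
        tau[inside & bar] += mu_eff["lamella"] * phantom.lamella_thickness_mm
    for h in phantom.contrast_holes:
        r2 = (X - h.center[0]) ** 2 + (Y - h.center[1]) ** 2
        tau[r2 <= (h.diameter_mm / 2.0) ** 2] += mu_eff["hole"] * h.depth_mm
    return tau


def effective_mu_map(phantom: PhantomSpec, beam: BeamSpectrum) -> dict[str, float]:
    """Effective (spectrum-weighted mean) μ̄, 1/mm, per phantom material role."""
    return {
        "base": effective_mu(beam, material_mu(phantom.base_material)),
        "lamella": effective_mu(beam, material_mu(phantom.lamella_material)),
        "hole": effective_mu(beam, material_mu(phantom.hole_material)),
    }


def render_phantom_image(phantom: PhantomSpec,
                         beam: BeamSpectrum,
                         geom: ImagingGeometry,
                         det: DetectorModel,
                         seed: int,
                         beam_mode: str = "al_target",
                         supersample: int = 1) -> PortalImage:
    """Render a portal image of the phantom.

    Pipeline: ideal transmission per pixel (effective-μ̄ Beer–Lambert through
    base slab, brass bars and aluminum discs), projective magnification
    sid/ssd, Gaussian PSF, scaled-Poisson + Gaussian noise, 16-bit
    quantization.  Identical inputs and seed give bit-identical output.

    ``supersample`` > 1 evaluates the geometry and blur on a finer grid and
    box-averages down (pixel-aperture integration); the default point-samples
    at pixel centres, which keeps noiseless bar/hole regions exactly
    two-level.
    """
    x0, x1, y0, y1 = phantom.bbox()
    fx, fy = geom.field_size_cm[0] * 10.0, geom.field_size_cm[1] * 10.0
    if max(abs(x0), abs(x1)) > fx / 2.0 or max(abs(y0), abs(y1)) > fy / 2.0:
        raise GeometryError("radiation field is smaller than the phantom footprint")
    if supersample < 1:
        raise DomainError("supersample must be >= 1")

    m = magnification(geom)
    rows, cols = _canvas_shape(phantom, geom, det)
    s = supersample
    fine_spacing = det.pixel_spacing_mm / s
    ncol, nrow = cols * s, rows * s
    # imager-plane coordinates of fine-pixel centres, mapped to phantom plane
    cx, cy = (ncol - 1) / 2.0, (nrow - 1) / 2.0
    x_mm = (np.arange(ncol) - cx) * fine_spacing / m
    y_mm = (cy - np.arange(nrow)) * fine_spacing / m

    mu_eff = effective_mu_map(phantom, beam)
    tau = _optical_depth(phantom, mu_eff, x_mm, y_mm)
    img = det.gain * np.exp(-tau)

    if det.psf_sigma_mm > 0:
        img = ndimage.gaussian_filter(img, det.psf_sigma_mm / fine_spacing,
                                      mode="nearest")
    if s > 1:
        img = img.reshape(rows, s, cols, s).mean(axis=(1, 3))

    rng = np.random.default_rng(seed)
    if det.poisson_scale > 0:
        img = rng.poisson(img / det.poisson_scale) * det.poisson_scale
    if det.gaussian_sigma > 0:
        img = img + rng.normal(0.0, det.gaussian_sigma, size=img.shape)

    top = 2 ** det.bit_depth - 1
    pixels = np.clip(np.rint(img), 0, top).astype(np.uint16)

    t_bg = math.exp(-mu_eff["base"] * phantom.base_thickness_mm)
    t_bar = t_bg * math.exp(-mu_eff["lamella"] * phantom.lamella_thickness_mm)
    meta = {
        "seed": int(seed),
        "psf_sigma_mm": det.psf_sigma_mm,
        "noise": {"poisson_scale": det.poisson_scale,
                  "gaussian_sigma": det.gaussian_sigma},
        "mu_eff_per_mm": mu_eff,
        "object_contrast": (t_bg - t_bar) / (t_bg + t_bar),
        "supersample": s,
    }
    return PortalImage(pixels=pixels, pixel_spacing_mm=det.pixel_spacing_mm,
                       beam_mode=beam_mode, inverted=False, meta=meta)


def render_beam_mode(phantom: PhantomSpec, geom: ImagingGeometry, mode: str,
                     seed: int, scale: float = 1.0, noise: bool = True,
                     canvas: Literal["cr", "phantom"] = "phantom",
                     psf_sigma_mm: float | None = None) -> PortalImage:
    """Convenience wrapper: default spectrum + detector for a beam mode."""
    beam = make_toy_spectrum(mode)
    det = default_detector(mode, scale=scale, canvas=canvas, noise=noise,
                           psf_sigma_mm=psf_sigma_mm)
    return render_phantom_image(phantom, beam, geom, det, seed=seed,
                                beam_mode=mode)


# ---------------------------------------------------------------------------
# dose-curve fixtures

def _pdd_shape(depth_range_mm: tuple[float, float] = (0.0, 300.0),
               spacing_mm: float = 2.0, buildup_mm: float = 5.0,
               falloff_per_mm: float = 0.005) -> DoseProfile1D:
    z = np.arange(depth_range_mm[0], depth_range_mm[1] + 0.5 * spacing_mm,
                  spacing_mm)
    d = (1.0 - np.exp(-z / buildup_mm)) * np.exp(-falloff_per_mm * z)
    d = 100.0 * d / d.max()
    return DoseProfile1D(z, d, kind="pdd", normalization="none")


def _lateral_shape(half_range_mm: float = 160.0, spacing_mm: float = 2.0,
                   field_width_mm: float = 200.0,
                   penumbra_sigma_mm: float = 5.0) -> DoseProfile1D:
    from scipy.special import erf
    x = np.arange(-half_range_mm, half_range_mm + 0.5 * spacing_mm, spacing_mm)
    e = 0.5 * (erf((x + field_width_mm / 2) / (penumbra_sigma_mm * np.sqrt(2)))
               - erf((x - field_width_mm / 2) / (penumbra_sigma_mm * np.sqrt(2))))
    d = 2.0 + 98.0 * e  # small out-of-field leakage keeps dose positive
    return DoseProfile1D(x, d, kind="lateral", normalization="none")


def make_dose_curve_pair(shape: Literal["pdd", "lateral"] | DoseProfile1D,
                         perturbation: tuple[float, float, float] = (0.0, 0.0, 0.0),
                         seed: int = 0,
                         **shape_params) -> tuple[DoseProfile1D, DoseProfile1D]:
    """Generate a (reference, evaluated) dose-curve pair.

    ``perturbation`` is (dose_offset_percent, spatial_shift_mm, noise_sigma):
    the evaluated curve is the reference scaled by (1 + offset/100), shifted
    by +shift mm, with additive Gaussian noise of the given sigma (same dose
    units as the curve).  Metadata on both curves records the perturbation.
    """
    if isinstance(shape, DoseProfile1D):
        ref = shape
    elif shape == "pdd":
        ref = _pdd_shape(**shape_params)
    elif shape == "lateral":
        ref = _lateral_shape(**shape_params)
    else:
        raise DomainError(f"unknown shape {shape!r}")
    offset, shift, noise_sigma = perturbation
    rng = np.random.default_rng(seed)
    dose = ref.dose * (1.0 + offset / 100.0)
    if noise_sigma > 0:
        dose = np.clip(dose + rng.normal(0.0, noise_sigma, size=dose.shape), 0, None)
    meta = {"perturbation": {"dose_offset_percent": offset,
                             "spatial_shift_mm": shift,
                             "noise_sigma": noise_sigma},
            "seed": int(seed)}
    ref = DoseProfile1D(ref.positions_mm, ref.dose, kind=ref.kind,
                        normalization=ref.normalization, meta=dict(meta))
    ev = DoseProfile1D(ref.positions_mm + shift, dose, kind=ref.kind,
                       normalization=ref.normalization, meta=dict(meta))
    return ref, ev
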