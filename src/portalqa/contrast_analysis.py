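"""Contrast-detail analysis of the 27 low-contrast elements.

Each element is scored by its relative contrast difference

    contrast difference = |E - E0| / E0,

where E is the mean detector signal over a concentric disc covering 80% of
the element's projected diameter and E0 the mean over a concentric background
annulus from 120% to 160% of the projected diameter.  Under the effective-μ
image formation the expected value is 1 - exp(-Δμ·t) with t the element
thickness.

Visibility is classified with the conventional three-band rule:
distinguishable (green) at >= 5%, barely distinguishable (yellow) at
3–5%, indistinguishable (red) below 3%; both boundaries inclusive on the
lower side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, LayoutError
from .image_synth import PortalImage
from .phantom_model import ContrastHole, ImagingGeometry, PhantomSpec, magnification

#: visibility thresholds on the contrast difference
GREEN_THRESHOLD = 0.05
YELLOW_THRESHOLD = 0.03

#: ROI geometry relative to the projected element diameter
MEASUREMENT_DIAMETER_FRACTION = 0.80
ANNULUS_INNER_FRACTION = 1.20
ANNULUS_OUTER_FRACTION = 1.60


def contrast_difference(E: float, E0: float) -> float:
    """Relative contrast difference |E - E0| / E0."""
    if E0 <= 0:
        raise DomainError("background signal E0 must be positive")
    if E < 0:
        raise DomainError("signal E must be non-negative")
    return abs(E - E0) / E0


def predicted_contrast(delta_mu_per_mm: float, t_mm: float) -> float:
    """Model contrast 1 - exp(-Δμ·t) of an element of thickness t."""
    if t_mm < 0:
        raise DomainError("thickness must be >= 0")
    return 1.0 - math.exp(-delta_mu_per_mm * t_mm)


def classify_contrast(value: float) -> str:
    """Three-band visibility label: green (>=5%), yellow ([3%,5%)), red (<3%)."""
    if value < 0:
        raise DomainError("contrast difference cannot be negative")
    if value >= GREEN_THRESHOLD:
        return "green"
    if value >= YELLOW_THRESHOLD:
        return "yellow"
    return "red"


@dataclass(frozen=True)
class HoleMeasurement:
    hole: ContrastHole
    E: float
    E0: float

    @property
    def contrast_difference(self) -> float:
        return contrast_difference(self.E, self.E0)

    @property
    def label(self) -> str:
        return classify_contrast(self.contrast_difference)


@dataclass(frozen=True)
class ContrastDetailResult:
    measurements: tuple[HoleMeasurement, ...]

    @property
    def counts(self) -> tuple[int, int, int]:
        """(n_green, n_yellow, n_red)."""
        labels = [m.label for m in self.measurements]
        return (labels.count("green"), labels.count("yellow"), labels.count("red"))

    def to_dict(self) -> dict:
        g, y, r = self.counts
        return {
            "holes": [
                {"diameter_mm": m.hole.diameter_mm, "depth_mm": m.hole.depth_mm,
                 "E": m.E, "E0": m.E0,
                 "contrast_difference": m.contrast_difference, "label": m.label}
                for m in self.measurements
            ],
            "counts": {"green": g, "yellow": y, "red": r},
        }


def contrast_detail_distribution(image: PortalImage, phantom: PhantomSpec,
                                 geom: ImagingGeometry) -> ContrastDetailResult:
    """Measure and classify every contrast element of the phantom."""
    m = magnification(geom)
    sp = image.pixel_spacing_mm
    rows, cols = image.shape
    cx, cy = (cols - 1) / 2.0, (rows - 1) / 2.0
    out = []
    for h in phantom.contrast_holes:
        cc = cx + h.center[0] * m / sp
        rc = cy - h.center[1] * m / sp
        d_px = h.diameter_mm * m / sp
        r_meas = 0.5 * MEASUREMENT_DIAMETER_FRACTION * d_px
        r_in = 0.5 * ANNULUS_INNER_FRACTION * d_px
        r_out = 0.5 * ANNULUS_OUTER_FRACTION * d_px
        r0 = int(math.floor(rc - r_out)) - 1
        r1 = int(math.ceil(rc + r_out)) + 2
        c0 = int(math.floor(cc - r_out)) - 1
        c1 = int(math.ceil(cc + r_out)) + 2
        if r0 < 0 or c0 < 0 or r1 > rows or c1 > cols:
            raise LayoutError(
                f"element d={h.diameter_mm} t={h.depth_mm} ROI falls off-image")
        patch = image.pixels[r0:r1, c0:c1].astype(float)
        rr = np.arange(r0, r1)[:, None] - rc
        ccol = np.arange(c0, c1)[None, :] - cc
        dist = np.hypot(rr, ccol)
        E = float(patch[dist <= r_meas].mean())
        E0 = float(patch[(dist >= r_in) & (dist <= r_out)].mean())
        out.append(HoleMeasurement(hole=h, E=E, E0=E0))
    return ContrastDetailResult(measurements=tuple(out))
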