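"""Geometry of the QC phantom's test elements and the imaging setup.

The phantom carries two groups of test objects:

* high-contrast resolution: brass lamella (bar-pattern) blocks with equal bar
  and gap width w, i.e. spatial frequency 1/(2w) in line pairs per mm, at 11
  distinct frequencies from 0.125 to 3.33 lp/mm;
* low-contrast detail: 27 circular aluminum measurement areas combining six
  diameters (15, 10, 7, 4, 2, 1.1 mm) and five thicknesses (0.5, 1.0, 2.0,
  3.2, 4.8 mm) — thickness sets the contrast, diameter the detail size.

Only the element dimensions are published for the commercial phantom; the
in-plane layout used here is a documented synthetic arrangement (bar blocks in
two rows, holes on a diameter-column × depth-row grid) chosen so every
element's background annulus clears its neighbours.

Coordinate convention: phantom-plane millimetres, origin at the phantom
centre, x rightward, y toward the gantry.  Images are row-major with 0-based
pixel indices; +y maps to decreasing row index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .errors import DomainError, GeometryError

#: printed (bar width mm, frequency lp/mm) pairs of the high-contrast table
PRINTED_LAMELLA_TABLE: list[tuple[float, str]] = [
    (4.0, "0.125"),
    (3.0, "0.167"),
    (2.0, "0.25"),
    (1.5, "0.33"),
    (1.0, "0.5"),
    (0.75, "0.67"),
    (0.5, "1"),
    (0.35, "1.43"),
    (0.25, "2"),
    (0.2, "2.5"),
    (0.15, "3.33"),
]

#: hole diameter (mm) -> available depths (mm) of the low-contrast table
HOLE_TABLE: dict[float, tuple[float, ...]] = {
    15.0: (0.5, 1.0, 2.0),
    10.0: (0.5, 1.0, 2.0, 3.2),
    7.0: (0.5, 1.0, 2.0, 3.2, 4.8),
    4.0: (0.5, 1.0, 2.0, 3.2, 4.8),
    2.0: (0.5, 1.0, 2.0, 3.2, 4.8),
    1.1: (0.5, 1.0, 2.0, 3.2, 4.8),
}


def lamella_frequency(width_mm: float) -> float:
    """Spatial frequency of an equal bar/gap pattern: 1/(2·width), lp/mm."""
    if width_mm <= 0:
        raise DomainError("lamella width must be positive")
    return 1.0 / (2.0 * width_mm)


@dataclass(frozen=True)
class LamellaBlock:
    """One bar-pattern block: bars and gaps of equal width.

    The pattern spans ``n_periods`` periods along the modulation axis,
    centred at ``center``; bars extend ``bar_length_mm`` transversely.
    ``orientation_deg`` rotates the modulation axis from +x.
    """

    width_mm: float
    center: tuple[float, float] = (0.0, 0.0)
    n_periods: int = 4
    bar_length_mm: float = 13.0
    orientation_deg: float = 0.0

    def __post_init__(self):
        if self.width_mm <= 0:
            raise DomainError("lamella width must be positive")
        if self.n_periods < 2:
            raise DomainError("a block needs at least 2 periods")

    @property
    def frequency(self) -> float:
        return lamella_frequency(self.width_mm)

    @property
    def period_mm(self) -> float:
        return 2.0 * self.width_mm

    @property
    def pattern_length_mm(self) -> float:
        return self.n_periods * self.period_mm


@dataclass(frozen=True)
class ContrastHole:
    """One low-contrast element: an aluminum disc of given diameter/thickness.

    Modelled as *added* attenuator over the base slab so the measurement area
    reads darker than its background, matching the contrast-difference model
    1 - exp(-Δμ·t).
    """

    diameter_mm: float
    depth_mm: float
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.diameter_mm <= 0 or self.depth_mm <= 0:
            raise DomainError("hole diameter and depth must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    """Full phantom description: bar blocks, contrast holes, materials."""

    lamella_blocks: tuple[LamellaBlock, ...]
    contrast_holes: tuple[ContrastHole, ...]
    base_material: str = "acrylic"
    base_thickness_mm: float = 20.0
    lamella_material: str = "brass"
    lamella_thickness_mm: float = 2.0
    hole_material: str = "aluminum"

    def __post_init__(self):
        object.__setattr__(self, "lamella_blocks", tuple(self.lamella_blocks))
        object.__setattr__(self, "contrast_holes", tuple(self.contrast_holes))

    def bbox(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of all elements, phantom-plane mm."""
        import math

        xs, ys = [], []
        for b in self.lamella_blocks:
            th = math.radians(b.orientation_deg)
            hu, hv = b.pattern_length_mm / 2.0, b.bar_length_mm / 2.0
            ex = abs(math.cos(th)) * hu + abs(math.sin(th)) * hv
            ey = abs(math.sin(th)) * hu + abs(math.cos(th)) * hv
            xs += [b.center[0] - ex, b.center[0] + ex]
            ys += [b.center[1] - ey, b.center[1] + ey]
        for h in self.contrast_holes:
            r = 0.5 * h.diameter_mm
            xs += [h.center[0] - r, h.center[0] + r]
            ys += [h.center[1] - r, h.center[1] + r]
        if not xs:
            raise DomainError("phantom has no elements")
        return min(xs), max(xs), min(ys), max(ys)

    def to_dict(self) -> dict:
        return {
            "base_material": self.base_material,
            "base_thickness_mm": self.base_thickness_mm,
            "lamella_material": self.lamella_material,
            "lamella_thickness_mm": self.lamella_thickness_mm,
            "hole_material": self.hole_material,
            "lamellae": [
                {"width_mm": b.width_mm, "position": list(b.center),
                 "n_periods": b.n_periods, "bar_length_mm": b.bar_length_mm,
                 "orientation_deg": b.orientation_deg}
                for b in self.lamella_blocks
            ],
            "holes": [
                {"diameter_mm": h.diameter_mm, "depth_mm": h.depth_mm,
                 "position": list(h.center)}
                for h in self.contrast_holes
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        blocks = tuple(
            LamellaBlock(width_mm=b["width_mm"], center=tuple(b["position"]),
                         n_periods=b.get("n_periods", 4),
                         bar_length_mm=b.get("bar_length_mm", 13.0),
                         orientation_deg=b.get("orientation_deg", 0.0))
            for b in d["lamellae"])
        holes = tuple(
            ContrastHole(diameter_mm=h["diameter_mm"], depth_mm=h["depth_mm"],
                         center=tuple(h["position"]))
            for h in d["holes"])
        return cls(lamella_blocks=blocks, contrast_holes=holes,
                   base_material=d.get("base_material", "acrylic"),
                   base_thickness_mm=d.get("base_thickness_mm", 20.0),
                   lamella_material=d.get("lamella_material", "brass"),
                   lamella_thickness_mm=d.get("lamella_thickness_mm", 2.0),
                   hole_material=d.get("hole_material", "aluminum"))


@dataclass(frozen=True)
class ImagingGeometry:
    """Projection geometry: source–surface and source–imager distances (cm)."""

    ssd_cm: float = 95.2
    sid_cm: float = 110.0
    field_size_cm: tuple[float, float] = (26.0, 26.0)

    def __post_init__(self):
        if not (self.sid_cm >= self.ssd_cm > 0):
            raise GeometryError("need sid >= ssd > 0")


def magnification(geom: ImagingGeometry) -> float:
    """Projection magnification sid/ssd (phantom plane -> imager plane)."""
    return geom.sid_cm / geom.ssd_cm


def _pack_row(widths: Iterable[float], y: float, gap_mm: float = 8.0,
              orientation_deg: float = 0.0) -> list[LamellaBlock]:
    """Place blocks left-to-right in one row, centred on x = 0."""
    widths = list(widths)
    lengths = [LamellaBlock(w).pattern_length_mm for w in widths]
    total = sum(lengths) + gap_mm * (len(widths) - 1)
    x = -total / 2.0
    blocks = []
    for w, L in zip(widths, lengths):
        blocks.append(LamellaBlock(width_mm=w, center=(x + L / 2.0, y),
                                   orientation_deg=orientation_deg))
        x += L + gap_mm
    return blocks


#: synthetic layout constants (mm)
_HOLE_COLUMN_X = {15.0: -65.0, 10.0: -39.0, 7.0: -13.0, 4.0: 13.0, 2.0: 39.0, 1.1: 65.0}
_HOLE_ROW_Y = {0.5: -14.0, 1.0: -40.0, 2.0: -66.0, 3.2: -92.0, 4.8: -118.0}


def default_ptw_phantom(variant: str = "11") -> PhantomSpec:
    """The default phantom: full published element tables, synthetic layout.

    ``variant="11"`` carries one block per distinct frequency; ``"14"`` adds
    duplicates of the three lowest frequencies in diagonal (45°) orientation,
    matching the physical phantom's 14 lamella sets without asserting the
    vendor's true arrangement.
    """
    if variant not in ("11", "14"):
        raise DomainError(f"variant must be '11' or '14', got {variant!r}")
    row1 = _pack_row([w for w, _ in PRINTED_LAMELLA_TABLE[:5]], y=50.0)
    row2 = _pack_row([w for w, _ in PRINTED_LAMELLA_TABLE[5:]], y=28.0)
    blocks = row1 + row2
    if variant == "14":
        blocks += _pack_row([4.0, 3.0, 2.0], y=76.0, orientation_deg=45.0)
    holes = [
        ContrastHole(diameter_mm=d, depth_mm=t,
                     center=(_HOLE_COLUMN_X[d], _HOLE_ROW_Y[t]))
        for d, depths in HOLE_TABLE.items()
        for t in depths
    ]
    return PhantomSpec(lamella_blocks=tuple(blocks), contrast_holes=tuple(holes))
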