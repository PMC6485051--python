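"""File I/O: 16-bit images with JSON sidecars, dose-profile CSVs, YAML config."""

from __future__ import annotations

import csv
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .errors import ConfigError, ProfileFormatError
from .gamma_analysis import DoseProfile1D
from .image_synth import PortalImage

_IMAGE_SUFFIXES = {".tif", ".tiff", ".png"}


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_image(image: PortalImage, path: str | Path) -> Path:
    """Write a 16-bit single-channel TIFF/PNG plus a JSON metadata sidecar."""
    path = Path(path)
    if path.suffix.lower() not in _IMAGE_SUFFIXES:
        raise ConfigError(f"unknown image extension {path.suffix!r}; use .tif or .png")
    pixels = np.asarray(image.pixels, dtype=np.uint16)
    if path.suffix.lower() == ".png":
        iio.imwrite(path, pixels)
    else:
        tifffile.imwrite(path, pixels)
    meta = {
        "beam_mode": image.beam_mode,
        "pixel_spacing_mm": image.pixel_spacing_mm,
        "inverted": image.inverted,
        **image.meta,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2, default=float))
    return path


def read_image(path: str | Path) -> PortalImage:
    """Read an image written by :func:`write_image` (lossless round-trip)."""
    path = Path(path)
    if path.suffix.lower() not in _IMAGE_SUFFIXES:
        raise ConfigError(f"unknown image extension {path.suffix!r}; use .tif or .png")
    if path.suffix.lower() == ".png":
        pixels = np.asarray(iio.imread(path))
    else:
        pixels = tifffile.imread(path)
    if pixels.dtype != np.uint16:
        raise ProfileFormatError(
            f"{path.name}: expected 16-bit grayscale, got dtype {pixels.dtype}")
    meta = {}
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return PortalImage(
        pixels=pixels,
        pixel_spacing_mm=float(meta.pop("pixel_spacing_mm", 1.0)),
        beam_mode=meta.pop("beam_mode", "unknown"),
        inverted=bool(meta.pop("inverted", False)),
        meta=meta,
    )


def write_profile(profile: DoseProfile1D, path: str | Path) -> Path:
    """Write a two-column `position_mm,dose` CSV with header."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["position_mm", "dose"])
        for x, d in zip(profile.positions_mm, profile.dose):
            w.writerow([repr(float(x)), repr(float(d))])
    if profile.meta:
        _sidecar(path).write_text(json.dumps(profile.meta, indent=2, default=float))
    return path


def read_profile(path: str | Path, kind: str = "lateral") -> DoseProfile1D:
    """Read a `position_mm,dose` CSV; malformed rows are reported by line."""
    path = Path(path)
    positions, dose = [], []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:2]] != ["position_mm", "dose"]:
            raise ProfileFormatError(
                f"{path.name}: line 1: expected header 'position_mm,dose'")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                positions.append(float(row[0]))
                dose.append(float(row[1]))
            except (ValueError, IndexError):
                raise ProfileFormatError(
                    f"{path.name}: line {lineno}: expected two numeric fields, "
                    f"got {row!r}") from None
    x = np.asarray(positions)
    if len(x) and not np.all(np.diff(x) > 0):
        bad = int(np.argmin(np.diff(x))) + 3  # header + 1-based + offset
        raise ProfileFormatError(
            f"{path.name}: line {bad}: positions must be strictly increasing")
    meta = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    return DoseProfile1D(x, np.asarray(dose), kind=kind, meta=meta)


def read_config(path: str | Path) -> dict:
    """Load a YAML config file as a nested dict (must be a mapping)."""
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path.name}: invalid YAML: {exc}") from None
    if not isinstance(data, dict):
        raise ConfigError(f"{path.name}: config root must be a mapping")
    return data
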