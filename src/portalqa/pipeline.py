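"""End-to-end orchestration: config -> simulate -> analyse -> comparison report.

``run_comparison`` renders one portal image per requested beam mode with a
shared seed, runs the bar-pattern MTF and contrast-detail analyses on each,
and assembles a report mirroring the study structure: per-beam MTF curves
with critical/limiting frequencies and per-beam visibility counts, plus
provenance (config hash, seed, package version).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .contrast_analysis import ContrastDetailResult, contrast_detail_distribution
from .errors import ConfigError
from .image_synth import PortalImage, render_beam_mode
from .phantom_model import ImagingGeometry, PhantomSpec, default_ptw_phantom
from .resolution_analysis import MTFCurve, compute_mtf_curve

DEFAULT_CONFIG = {
    "beam": {"modes": ["al_target", "6mv"], "max_energy_kev": 6000},
    "detector": {"scale": 1.0, "canvas": "phantom", "noise": True},
    "phantom": {"variant": "11"},
    "geometry": {"ssd_cm": 95.2, "sid_cm": 110.0, "field_size_cm": [26.0, 26.0]},
    "analysis": {"mtf_levels": [0.5, 0.1],
                 "contrast_thresholds": [0.05, 0.03],
                 "gamma": {"dose_tolerance_percent": 3.0, "dta_mm": 3.0,
                           "resample_spacing_mm": 1.0}},
    "seed": 0,
}


@dataclass(frozen=True)
class RunConfig:
    beam_modes: tuple[str, ...]
    seed: int
    scale: float = 1.0
    canvas: str = "phantom"
    noise: bool = True
    phantom_variant: str = "11"
    geometry: ImagingGeometry = field(default_factory=ImagingGeometry)
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        def need(section: str, key: str):
            try:
                return cfg[section][key]
            except (KeyError, TypeError):
                raise ConfigError(f"missing config key '{section}.{key}'") from None

        modes = need("beam", "modes")
        if isinstance(modes, str):
            modes = [modes]
        det = cfg.get("detector", {})
        geo = cfg.get("geometry", {})
        geom = ImagingGeometry(
            ssd_cm=float(geo.get("ssd_cm", 95.2)),
            sid_cm=float(geo.get("sid_cm", 110.0)),
            field_size_cm=tuple(geo.get("field_size_cm", (26.0, 26.0))),
        )
        if "seed" not in cfg:
            raise ConfigError("missing config key 'seed'")
        return cls(beam_modes=tuple(modes), seed=int(cfg["seed"]),
                   scale=float(det.get("scale", 1.0)),
                   canvas=str(det.get("canvas", "phantom")),
                   noise=bool(det.get("noise", True)),
                   phantom_variant=str(cfg.get("phantom", {}).get("variant", "11")),
                   geometry=geom, raw=cfg)

    def hash(self) -> str:
        blob = json.dumps(self.raw or self.canonical_dict(), sort_keys=True,
                          default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def canonical_dict(self) -> dict:
        return {"beam": {"modes": list(self.beam_modes)},
                "detector": {"scale": self.scale, "canvas": self.canvas,
                             "noise": self.noise},
                "phantom": {"variant": self.phantom_variant},
                "geometry": {"ssd_cm": self.geometry.ssd_cm,
                             "sid_cm": self.geometry.sid_cm,
                             "field_size_cm": list(self.geometry.field_size_cm)},
                "seed": self.seed}


@dataclass(frozen=True)
class BeamArm:
    mode: str
    image: PortalImage
    mtf: MTFCurve
    contrast: ContrastDetailResult


@dataclass(frozen=True)
class ComparisonReport:
    arms: tuple[BeamArm, ...]
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "beams": {
                arm.mode: {
                    "mtf": arm.mtf.to_dict(),
                    "contrast_detail": arm.contrast.to_dict(),
                }
                for arm in self.arms
            },
        }

    def mtf_table(self) -> pd.DataFrame:
        frames = []
        for arm in self.arms:
            frames.append(pd.DataFrame({
                "beam_mode": arm.mode,
                "frequency_lp_per_mm": arm.mtf.frequencies,
                "mtf_raw": arm.mtf.mtf_raw,
                "mtf_relative": arm.mtf.mtf_relative,
            }))
        return pd.concat(frames, ignore_index=True)

    def contrast_table(self) -> pd.DataFrame:
        rows = []
        for arm in self.arms:
            for m in arm.contrast.measurements:
                rows.append({"beam_mode": arm.mode,
                             "diameter_mm": m.hole.diameter_mm,
                             "depth_mm": m.hole.depth_mm,
                             "E": m.E, "E0": m.E0,
                             "contrast_difference": m.contrast_difference,
                             "label": m.label})
        return pd.DataFrame(rows)


def run_comparison(config: RunConfig | dict) -> ComparisonReport:
    """Simulate and analyse each configured beam mode with a shared seed."""
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    phantom = default_ptw_phantom(config.phantom_variant)
    arms = []
    for mode in config.beam_modes:
        image = render_beam_mode(phantom, config.geometry, mode,
                                 seed=config.seed, scale=config.scale,
                                 noise=config.noise, canvas=config.canvas)
        mtf = compute_mtf_curve(image, phantom, config.geometry)
        cd = contrast_detail_distribution(image, phantom, config.geometry)
        arms.append(BeamArm(mode=mode, image=image, mtf=mtf, contrast=cd))
    provenance = {"config_hash": config.hash(), "seed": config.seed,
                  "portalqa_version": __version__,
                  "config": config.canonical_dict()}
    return ComparisonReport(arms=tuple(arms), provenance=provenance)


def write_report(report: ComparisonReport, outdir: str | Path) -> dict[str, Path]:
    """Write the report as JSON plus MTF/contrast CSV tables; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "report": outdir / "comparison_report.json",
        "mtf": outdir / "mtf_curves.csv",
        "contrast": outdir / "contrast_detail.csv",
    }
    paths["report"].write_text(json.dumps(report.to_dict(), indent=2, default=float))
    report.mtf_table().to_csv(paths["mtf"], index=False)
    report.contrast_table().to_csv(paths["contrast"], index=False)
    return paths
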