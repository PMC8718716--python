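"""Pipeline configuration and stage orchestration.

Stages: simulate -> mask -> matchup -> calibrate -> patchmap. Each stage
reads/writes files under an output directory; ``run_all`` chains them on
synthetic data end to end. Every output carries the config hash so runs
are auditable and reproducible under fixed seeds.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import flags as flg
from . import io as lio
from . import synthetic_data as synth
from .calibration import CalibrationCoefficients, fit_regional_coefficients
from .geometry import LakeGeometry, build_valid_water_mask, mask_to_polygon
from .matchup import build_matchups
from .spatial_stats import compute_composite

log = logging.getLogger(__name__)

STAGES = ("simulate", "mask", "matchup", "calibrate", "patchmap", "all")


@dataclass
class PipelineConfig:
    """All tunable constants of the pipeline (defaults as published)."""

    buffer_distance: float = 120.0
    secchi_quantile: float = 0.95
    matchup_window_hours: float = 24.0
    macropixel_size: int = 3
    min_valid: int = 6
    homogeneity_threshold: float = 0.20
    band_tolerance: float = 0.05
    coverage_threshold: float = 0.5
    coefficients: tuple[float, float, float] = (21.0, 0.77, 1.04)
    seed: int = 0
    # synthetic-mode knobs
    rows: int = 60
    cols: int = 60
    cell_size: float = 60.0
    lake_radius_m: float = 1500.0
    max_depth_m: float = 30.0
    base_chl: float = 10.0
    n_scenes: int = 40
    cadence_days: float = 5.0
    cloud_fraction: float = 0.2
    noise_cv: float = 0.1
    temporal_cv: float = 0.2
    measurement_cv: float = 0.05
    n_stations: int = 3
    n_secchi: int = 200
    secchi_median_m: float = 4.0
    secchi_sigma: float = 0.4

    def __post_init__(self) -> None:
        if not (0 < self.secchi_quantile < 1):
            raise ValueError("secchi_quantile must be in (0, 1)")
        if self.homogeneity_threshold <= 0 or self.band_tolerance < 0:
            raise ValueError("thresholds must be positive")
        if not (0 <= self.coverage_threshold <= 1):
            raise ValueError("coverage_threshold must be in [0, 1]")
        if self.min_valid < 1 or self.macropixel_size % 2 != 1:
            raise ValueError("min_valid >= 1 and odd macropixel_size required")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["coefficients"] = list(d["coefficients"])
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "coefficients" in doc:
            doc["coefficients"] = tuple(doc["coefficients"])
        return cls(**doc)


@dataclass
class StageCounts:
    """Per-stage record accounting, emitted to the log and provenance."""

    counts: dict = field(default_factory=dict)

    def set(self, **kw) -> None:
        self.counts.update(kw)
        for k, v in kw.items():
            log.info("%s = %s", k, v)


def _paths(outdir: Path) -> dict[str, Path]:
    return {
        "scenes": outdir / "scenes.nc",
        "insitu": outdir / "insitu.csv",
        "secchi": outdir / "secchi.csv",
        "lake_polygon": outdir / "lake_outline.geojson",
        "bathymetry": outdir / "bathymetry.tif",
        "valid_water": outdir / "valid_water.geojson",
        "matchups": outdir / "matchups.csv",
        "fit": outdir / "calibration_fit.json",
        "composite": outdir / "composite.tif",
        "provenance": outdir / "provenance.json",
    }


def _write_provenance(cfg: PipelineConfig, outdir: Path, stage: str,
                      counts: StageCounts) -> None:
    p = _paths(outdir)["provenance"]
    doc = json.loads(p.read_text()) if p.exists() else {}
    doc[stage] = {"config_hash": cfg.config_hash(), "config": cfg.to_dict(),
                  "counts": counts.counts}
    p.write_text(json.dumps(doc, sort_keys=True, indent=1))


def _build_synthetic_world(cfg: PipelineConfig):
    geometry = synth.generate_lake_geometry(
        cfg.rows, cfg.cols, cfg.cell_size,
        {"radius_m": cfg.lake_radius_m, "max_depth_m": cfg.max_depth_m},
        seed=cfg.seed,
    )
    geometry.buffer_distance = cfg.buffer_distance
    geometry.secchi_quantile = cfg.secchi_quantile
    truth = synth.make_lake_truth(
        geometry, base_chl=cfg.base_chl, n_scenes=cfg.n_scenes,
        temporal_cv=cfg.temporal_cv, noise_cv=cfg.noise_cv, seed=cfg.seed,
    )
    return geometry, truth


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> StageCounts:
    """Generate and write the full synthetic input set."""
    outdir.mkdir(parents=True, exist_ok=True)
    p = _paths(outdir)
    counts = StageCounts()
    geometry, truth = _build_synthetic_world(cfg)
    scenes = synth.generate_scene_series(
        truth, cloud_fraction=cfg.cloud_fraction,
        cadence_days=cfg.cadence_days, seed=cfg.seed + 1,
    )
    secchi = synth.generate_secchi_samples(
        cfg.n_secchi, median=cfg.secchi_median_m, sigma=cfg.secchi_sigma,
        seed=cfg.seed + 2,
    )
    lake_rows, lake_cols = np.nonzero(truth.lake_mask)
    deepest = np.argsort(truth.bathymetry[lake_rows, lake_cols])[::-1]
    stations = [(int(lake_rows[i]), int(lake_cols[i]))
                for i in deepest[: cfg.n_stations]]
    samples = synth.generate_insitu_survey(
        truth, scenes, stations, time_offsets_h=(-12.0, 12.0),
        measurement_cv=cfg.measurement_cv, seed=cfg.seed + 3,
    )
    lio.write_scene_series(scenes, p["scenes"])
    lio.write_insitu_csv(samples, p["insitu"])
    np.savetxt(p["secchi"], secchi, header="secchi_depth_m", comments="")
    lio.write_polygon_geojson(
        geometry.lake_polygon, p["lake_polygon"],
        {"kind": "lake_outline", "config_hash": cfg.config_hash()},
    )
    lio.write_geotiff(geometry.bathymetry, geometry.grid, p["bathymetry"],
                      band_names=["bathymetry_m"])
    counts.set(scenes_written=len(scenes), insitu_samples=len(samples),
               secchi_samples=len(secchi), lake_pixels=int(truth.lake_mask.sum()))
    _write_provenance(cfg, outdir, "simulate", counts)
    return counts


def _load_geometry(cfg: PipelineConfig, outdir: Path, grid) -> LakeGeometry:
    p = _paths(outdir)
    polygon, _ = lio.read_polygon_geojson(p["lake_polygon"])
    bathy, bgrid, _ = lio.read_geotiff(p["bathymetry"])
    from .geometry import rasterize_polygon
    lake_mask = rasterize_polygon(polygon, bgrid)
    return LakeGeometry(
        lake_polygon=polygon, grid=bgrid, lake_mask=lake_mask,
        bathymetry=bathy[0], buffer_distance=cfg.buffer_distance,
        secchi_quantile=cfg.secchi_quantile,
    )


def stage_mask(cfg: PipelineConfig, outdir: Path) -> StageCounts:
    """Build the valid-water mask and raise its flag in every scene."""
    p = _paths(outdir)
    counts = StageCounts()
    scenes = lio.read_scene_series(p["scenes"])
    geometry = _load_geometry(cfg, outdir, scenes[0].grid)
    secchi = np.loadtxt(p["secchi"], skiprows=1)
    mask = build_valid_water_mask(geometry, secchi)
    for scene in scenes:
        scene.flags = scene.flags & ~np.int32(flg.Flag.SHORE_SHALLOW_BUFFER)
        scene.flags = flg.set_flag(scene.flags, flg.Flag.SHORE_SHALLOW_BUFFER,
                                   mask)
    lio.write_scene_series(scenes, p["scenes"])
    lio.write_polygon_geojson(
        mask_to_polygon(mask, geometry.grid), p["valid_water"],
        {"kind": "valid_water", **{k: str(v) for k, v in geometry.meta.items()},
         "config_hash": cfg.config_hash()},
    )
    counts.set(valid_water_pixels=int(mask.sum()),
               lake_pixels=int(geometry.lake_mask.sum()),
               secchi_exclusion_depth_m=float(
                   geometry.meta["secchi_exclusion_depth_m"]))
    _write_provenance(cfg, outdir, "mask", counts)
    return counts


def stage_matchup(cfg: PipelineConfig, outdir: Path) -> StageCounts:
    p = _paths(outdir)
    counts = StageCounts()
    scenes = lio.read_scene_series(p["scenes"])
    samples = lio.read_insitu_csv(p["insitu"])
    records = build_matchups(
        samples, scenes, window_hours=cfg.matchup_window_hours,
        min_valid=cfg.min_valid,
        homogeneity_threshold=cfg.homogeneity_threshold,
        macropixel_size=cfg.macropixel_size,
    )
    lio.write_matchup_csv(records, p["matchups"])
    reasons: dict[str, int] = {}
    for r in records:
        if not r.passed:
            reasons[r.rejection_reason] = reasons.get(r.rejection_reason, 0) + 1
    counts.set(candidates=len(records),
               passed=sum(r.passed for r in records),
               rejected_by_reason=reasons)
    _write_provenance(cfg, outdir, "matchup", counts)
    return counts


def stage_calibrate(cfg: PipelineConfig, outdir: Path) -> StageCounts:
    import pandas as pd

    p = _paths(outdir)
    counts = StageCounts()
    df = pd.read_csv(p["matchups"])
    ok = df[df["passed"] & df["a_pig"].notna()]
    init = CalibrationCoefficients(*cfg.coefficients)
    result = fit_regional_coefficients(
        ok["a_pig"], ok["a_det"], ok["a_cdom"], ok["insitu_chl_mg_m3"],
        init=init,
    )
    doc = result.to_dict()
    doc["config_hash"] = cfg.config_hash()
    Path(p["fit"]).write_text(json.dumps(doc, sort_keys=True, indent=1))
    counts.set(matchups_used=result.n, r_squared=result.r_squared,
               rmse=result.rmse)
    _write_provenance(cfg, outdir, "calibrate", counts)
    return counts


def stage_patchmap(cfg: PipelineConfig, outdir: Path) -> StageCounts:
    p = _paths(outdir)
    counts = StageCounts()
    scenes = lio.read_scene_series(p["scenes"])
    geometry = _load_geometry(cfg, outdir, scenes[0].grid)
    secchi = np.loadtxt(p["secchi"], skiprows=1)
    build_valid_water_mask(geometry, secchi)
    composite = compute_composite(
        scenes, geometry, tolerance=cfg.band_tolerance,
        coverage_threshold=cfg.coverage_threshold,
    )
    composite.meta["config_hash"] = cfg.config_hash()
    lio.write_composite_geotiff(composite, p["composite"])
    counts.set(scenes_total=len(scenes),
               scenes_participating=composite.n_scenes)
    _write_provenance(cfg, outdir, "patchmap", counts)
    return counts


def run_stage(name: str, cfg: PipelineConfig, outdir: Path) -> None:
    outdir = Path(outdir)
    if name == "all":
        for stage in ("simulate", "mask", "matchup", "calibrate", "patchmap"):
            run_stage(stage, cfg, outdir)
        return
    stage_fn = {
        "simulate": stage_simulate,
        "mask": stage_mask,
        "matchup": stage_matchup,
        "calibrate": stage_calibrate,
        "patchmap": stage_patchmap,
    }.get(name)
    if stage_fn is None:
        raise ValueError(f"unknown stage '{name}' (choose from {STAGES})")
    stage_fn(cfg, outdir)
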