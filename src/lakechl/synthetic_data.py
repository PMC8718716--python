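"""Synthetic lakes, IOP scene series and surveys with known ground truth.

Everything downstream of the satellite processor is testable without any
download: this module fabricates lake geometries with bathymetry, scene
time series whose IOP fields invert the regional Chl model exactly (so the
true per-pixel Chl is known), quality-flag layers with controllable cloud
contamination, Secchi-depth records, and in-situ surveys sampled from the
true field with measurement noise and time offsets.

Every generator is bit-reproducible under (inputs, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Point

from . import flags as flg
from .calibration import CANONICAL_COEFFICIENTS, CalibrationCoefficients
from .geometry import LakeGeometry, rasterize_polygon
from .grid import GridSpec, Scene
from .matchup import InSituSample

__all__ = [
    "LakeTruth",
    "SceneTruthParams",
    "generate_lake_geometry",
    "make_lake_truth",
    "generate_scene",
    "generate_scene_series",
    "generate_insitu_survey",
    "generate_secchi_samples",
    "gradient_pattern",
]

# Fraction of the inner absorption term assigned to pigment when inverting
# the Chl model; the remainder is split equally between detritus and CDOM.
PIGMENT_SHARE = 0.70


@dataclass
class LakeTruth:
    """Ground truth driving a synthetic scene series.

    ``pattern`` is a persistent multiplicative field with mean ~1 over the
    lake; ``temporal_factors`` are per-scene lake-wide multipliers;
    ``noise_cv`` is the coefficient of variation of the per-pixel,
    per-scene lognormal noise.
    """

    grid: GridSpec
    lake_mask: np.ndarray
    bathymetry: np.ndarray
    base_chl: float
    pattern: np.ndarray
    temporal_factors: np.ndarray
    noise_cv: float
    seed: int
    coefficients: CalibrationCoefficients = field(
        default_factory=lambda: CANONICAL_COEFFICIENTS
    )

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError(f"noise_cv must be >= 0, got {self.noise_cv}")
        if self.base_chl <= 0:
            raise ValueError("base_chl must be > 0")
        if np.any(self.bathymetry < 0):
            raise ValueError("bathymetry must be >= 0")
        if np.any(self.bathymetry[~self.lake_mask] != 0):
            raise ValueError("bathymetry must be 0 outside the lake mask")
        mean_pat = float(self.pattern[self.lake_mask].mean())
        if abs(mean_pat - 1.0) > 0.01:
            raise ValueError(
                f"pattern mean over lake must be within 1% of 1.0, got {mean_pat}"
            )


@dataclass
class SceneTruthParams:
    """Per-scene contamination controls."""

    timestamp: pd.Timestamp
    cloud_fraction: float = 0.0
    flag_noise_rates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamp = pd.Timestamp(self.timestamp)
        if self.timestamp.tzinfo is None:
            self.timestamp = self.timestamp.tz_localize("UTC")
        if not (0.0 <= self.cloud_fraction <= 1.0):
            raise ValueError("cloud_fraction must be in [0, 1]")
        for name, rate in self.flag_noise_rates.items():
            flag = flg.Flag[name]  # KeyError for unknown names
            if flag in flg.REQUIRED_FLAGS:
                raise ValueError(f"{name} is a required flag, not a noise flag")
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"noise rate for {name} must be in [0, 1]")


def generate_lake_geometry(
    rows: int,
    cols: int,
    cell_size: float = 60.0,
    lake_shape_params: Optional[dict] = None,
    seed: int = 0,
) -> LakeGeometry:
    """A circular/elliptical lake with smooth centre-deep bathymetry.

    ``lake_shape_params`` keys: ``radius_m`` (circle radius; default 40% of
    the shorter grid side), ``aspect`` (y/x semi-axis ratio, default 1),
    ``max_depth_m`` (default 30), ``center`` ((x, y), default grid centre).
    """
    if rows < 10 or cols < 10:
        raise ValueError("grid must be at least 10x10 cells")
    params = dict(lake_shape_params or {})
    grid = GridSpec(rows=rows, cols=cols, cell_size=cell_size)
    half_w = cols * cell_size / 2.0
    half_h = rows * cell_size / 2.0
    radius = float(params.get("radius_m", 0.4 * min(half_w, half_h) * 2))
    aspect = float(params.get("aspect", 1.0))
    max_depth = float(params.get("max_depth_m", 30.0))
    cx, cy = params.get("center", (grid.x0 + half_w, grid.y0 - half_h))

    if radius < 2.5 * cell_size or radius * aspect < 2.5 * cell_size:
        raise ValueError(
            f"degenerate lake (radius {radius} m < 5x5 cells at {cell_size} m): "
            "an inward shoreline buffer would erase it"
        )

    circle = Point(cx, cy).buffer(radius, quad_segs=256)
    if aspect != 1.0:
        from shapely import affinity
        polygon = affinity.scale(circle, xfact=1.0, yfact=aspect, origin=(cx, cy))
    else:
        polygon = circle
    lake_mask = rasterize_polygon(polygon, grid)
    if not lake_mask.any():
        raise ValueError("lake polygon contains no pixel centres")

    # smooth bowl: depth scales with distance-to-shore, deepest near centroid
    edt = ndimage.distance_transform_edt(lake_mask, sampling=cell_size)
    bathymetry = np.zeros(grid.shape, dtype=float)
    if edt.max() > 0:
        bathymetry = max_depth * (edt / edt.max())
    bathymetry[~lake_mask] = 0.0

    return LakeGeometry(
        lake_polygon=polygon,
        grid=grid,
        lake_mask=lake_mask,
        bathymetry=bathymetry,
        meta={"shape_params": params, "seed": seed},
    )


def gradient_pattern(lake_mask: np.ndarray, amplitude: float = 0.5,
                     axis: int = 1) -> np.ndarray:
    """Linear multiplicative ramp across the lake, normalized to mean 1.

    ``amplitude`` is the half-range of the ramp before normalization
    (0.5 -> roughly 0.5x to 1.5x across the lake extent).
    """
    rows, cols = lake_mask.shape
    n = cols if axis == 1 else rows
    ramp_1d = np.linspace(1.0 - amplitude, 1.0 + amplitude, n)
    pattern = np.tile(ramp_1d, (rows, 1)) if axis == 1 else \
        np.tile(ramp_1d[:, None], (1, cols))
    pattern = pattern / pattern[lake_mask].mean()
    return pattern


def make_lake_truth(
    geometry: LakeGeometry,
    base_chl: float = 10.0,
    pattern: Optional[np.ndarray] = None,
    n_scenes: int = 10,
    temporal_cv: float = 0.0,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> LakeTruth:
    """Assemble a :class:`LakeTruth` on an existing geometry.

    ``pattern=None`` plants a default west-east gradient. Temporal factors
    are lognormal with mean 1 and CV ``temporal_cv`` (all 1 when 0).
    """
    rng = np.random.default_rng(seed)
    if pattern is None:
        pattern = gradient_pattern(geometry.lake_mask)
    if temporal_cv > 0:
        sigma = np.sqrt(np.log1p(temporal_cv ** 2))
        factors = rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma, size=n_scenes)
    else:
        factors = np.ones(n_scenes)
    return LakeTruth(
        grid=geometry.grid,
        lake_mask=geometry.lake_mask,
        bathymetry=geometry.bathymetry,
        base_chl=base_chl,
        pattern=pattern,
        temporal_factors=factors,
        noise_cv=noise_cv,
        seed=seed,
    )


def _lognormal_factor(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative lognormal noise with mean exactly 1 and CV ``cv``."""
    if cv == 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv ** 2))
    return rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma, size=shape)


def _invert_iops(chl: np.ndarray, coeffs: CalibrationCoefficients
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """IOP triple whose forward model reproduces ``chl`` to round-off.

    The inner absorption term is (chl/A)^(1/C); a fixed share goes to
    pigment and the remainder, divided by B, splits equally between
    detritus and CDOM.
    """
    inner = np.power(chl / coeffs.scale, 1.0 / coeffs.exponent)
    a_pig = PIGMENT_SHARE * inner
    rest = (1.0 - PIGMENT_SHARE) * inner / coeffs.weight
    a_det = 0.5 * rest
    a_cdom = 0.5 * rest
    return a_pig, a_det, a_cdom


def generate_scene(
    truth: LakeTruth,
    params: SceneTruthParams,
    seed: int,
    temporal_factor: float = 1.0,
    valid_water_mask: Optional[np.ndarray] = None,
) -> Scene:
    """One synthetic scene: true Chl field, consistent IOPs, flag layers.

    Per-pixel true Chl = base_chl x pattern x temporal_factor x lognormal
    noise. Cloud contamination is a single random disc of area about
    ``cloud_fraction`` x lake area, with a 2-pixel cloud buffer. The water
    flag is raised on all lake pixels; if ``valid_water_mask`` is given the
    shoreline/shallow-water-buffer flag is raised there too.
    """
    if truth.noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    grid = truth.grid
    mask = truth.lake_mask

    noise = _lognormal_factor(rng, truth.noise_cv, grid.shape)
    chl = truth.base_chl * truth.pattern * temporal_factor * noise
    chl = np.where(mask, chl, np.nan)
    a_pig, a_det, a_cdom = _invert_iops(chl, truth.coefficients)

    bits = np.zeros(grid.shape, dtype=np.int32)
    bits = flg.set_flag(bits, flg.Flag.IDEPIX_WATER, mask)
    if valid_water_mask is not None:
        bits = flg.set_flag(bits, flg.Flag.SHORE_SHALLOW_BUFFER, valid_water_mask)

    if params.cloud_fraction > 0:
        n_lake = int(mask.sum())
        radius_cells = np.sqrt(params.cloud_fraction * n_lake / np.pi)
        lake_rows, lake_cols = np.nonzero(mask)
        i = rng.integers(len(lake_rows))
        cr, cc = lake_rows[i], lake_cols[i]
        rr, cc_idx = np.ogrid[: grid.rows, : grid.cols]
        cloud = (rr - cr) ** 2 + (cc_idx - cc) ** 2 <= radius_cells ** 2
        bits = flg.set_flag(bits, flg.Flag.IDEPIX_CLOUD, cloud)
        buffer_zone = flg.apply_cloud_buffer(cloud, width=2) & ~cloud
        bits = flg.set_flag(bits, flg.Flag.IDEPIX_CLOUD_BUFFER, buffer_zone)

    for name, rate in sorted(params.flag_noise_rates.items()):
        if rate > 0:
            where = mask & (rng.random(grid.shape) < rate)
            bits = flg.set_flag(bits, flg.Flag[name], where)

    return Scene(
        timestamp=params.timestamp,
        grid=grid,
        chl=chl,
        flags=bits,
        a_pig=a_pig,
        a_det=a_det,
        a_cdom=a_cdom,
        meta={"temporal_factor": temporal_factor, "seed": seed},
    )


def generate_scene_series(
    truth: LakeTruth,
    n_scenes: Optional[int] = None,
    start: str = "2016-01-01T00:00:00Z",
    cadence_days: float = 5.0,
    cloud_fraction: float = 0.0,
    flag_noise_rates: Optional[Mapping[str, float]] = None,
    valid_water_mask: Optional[np.ndarray] = None,
    seed: int = 0,
) -> list[Scene]:
    """Scene series at a fixed cadence, one child seed per scene."""
    if n_scenes is None:
        n_scenes = len(truth.temporal_factors)
    if n_scenes > len(truth.temporal_factors):
        raise ValueError("more scenes requested than temporal factors in truth")
    child_seeds = np.random.SeedSequence(seed).spawn(n_scenes)
    t0 = pd.Timestamp(start)
    scenes = []
    for k in range(n_scenes):
        params = SceneTruthParams(
            timestamp=t0 + pd.Timedelta(days=cadence_days * k),
            cloud_fraction=cloud_fraction,
            flag_noise_rates=dict(flag_noise_rates or {}),
        )
        scene_rng_seed = child_seeds[k].generate_state(1)[0]
        scenes.append(
            generate_scene(
                truth, params, seed=int(scene_rng_seed),
                temporal_factor=float(truth.temporal_factors[k]),
                valid_water_mask=valid_water_mask,
            )
        )
    return scenes


def generate_insitu_survey(
    truth: LakeTruth,
    scenes: Sequence[Scene],
    stations: Sequence[tuple[int, int]],
    time_offsets_h=0.0,
    measurement_cv: float = 0.0,
    seed: int = 0,
    lake_id: str = "synthetic",
    source: str = "monitoring",
) -> list[InSituSample]:
    """In-situ samples at grid stations, one per (station, scene).

    Each sample is the scene's true Chl at the station pixel times a
    lognormal measurement error (CV ``measurement_cv``), timestamped at the
    scene time plus an offset. ``time_offsets_h`` is a scalar (applied to
    every sample), a (lo, hi) tuple (uniform draws), or an array of shape
    (n_stations, n_scenes).
    """
    rng = np.random.default_rng(seed)
    n_st, n_sc = len(stations), len(scenes)
    for r, c in stations:
        if not (0 <= r < truth.grid.rows and 0 <= c < truth.grid.cols) \
                or not truth.lake_mask[r, c]:
            raise ValueError(f"station ({r}, {c}) is outside the lake mask")

    if np.isscalar(time_offsets_h):
        offsets = np.full((n_st, n_sc), float(time_offsets_h))
    elif isinstance(time_offsets_h, tuple) and len(time_offsets_h) == 2:
        lo, hi = time_offsets_h
        offsets = rng.uniform(lo, hi, size=(n_st, n_sc))
    else:
        offsets = np.asarray(time_offsets_h, dtype=float)
        if offsets.shape != (n_st, n_sc):
            raise ValueError(
                f"time_offsets_h array must have shape {(n_st, n_sc)}"
            )

    noise = _lognormal_factor(rng, measurement_cv, (n_st, n_sc))
    samples = []
    for i, (r, c) in enumerate(stations):
        x, y = truth.grid.index_to_xy(r, c)
        for j, scene in enumerate(scenes):
            chl_true = float(scene.chl[r, c])
            samples.append(
                InSituSample(
                    lake_id=lake_id,
                    station_id=f"ST{i:02d}",
                    x=x, y=y,
                    timestamp=scene.timestamp
                    + pd.Timedelta(hours=float(offsets[i, j])),
                    chl=chl_true * float(noise[i, j]),
                    source=source,
                )
            )
    return samples


def generate_secchi_samples(n: int, median: float = 5.0, sigma: float = 0.4,
                            seed: int = 0) -> np.ndarray:
    """Lognormal Secchi depths (metres): ``median * exp(N(0, sigma))``."""
    if n < 1:
        raise ValueError(f"need at least 1 Secchi sample, got n={n}")
    if median <= 0 or sigma < 0:
        raise ValueError("median must be > 0 and sigma >= 0")
    rng = np.random.default_rng(seed)
    return median * np.exp(rng.normal(0.0, sigma, size=n))
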