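"""Quantile-frequency composites identifying recurring spatial patterns.

Per scene (participating only when at least half of the lake's valid-water
pixels are unflagged), pixels are assigned to bands within +/-5% of the
scene's Q50, Q25 and Q75 of valid chlorophyll values. Band assignments
accumulated over the series become per-pixel relative frequencies (%):
pixels frequently near the median are representative sampling areas;
pixels frequently near the quartiles bracket the lake's spread.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import flags as flg
from .geometry import LakeGeometry, QUANTILE_METHOD
from .grid import GridSpec, Scene

__all__ = [
    "QuantileSummary",
    "CompositeFrequency",
    "BAND_NAMES",
    "scene_coverage",
    "lake_quantiles",
    "assign_quantile_bands",
    "accumulate_frequencies",
    "compute_composite",
]

log = logging.getLogger(__name__)

BAND_NAMES = ("near_median", "near_lower_quartile", "near_upper_quartile")
_BAND_KEYS = ("q50", "q25", "q75")


@dataclass(frozen=True)
class QuantileSummary:
    """Scene-level quantiles of valid chlorophyll values (mg m^-3)."""

    q25: float
    q50: float
    q75: float
    n_valid: int
    coverage: float

    def __post_init__(self) -> None:
        if not (self.q25 <= self.q50 <= self.q75):
            raise ValueError("quantiles must be ordered q25 <= q50 <= q75")
        if not (0.0 <= self.coverage <= 1.0):
            raise ValueError("coverage must be in [0, 1]")


@dataclass
class CompositeFrequency:
    """Per-pixel band frequencies in percent, plus provenance.

    ``band_q50`` / ``band_q25`` / ``band_q75`` are NaN where the pixel was
    never valid in any participating scene. ``denominator`` counts, per
    pixel, the participating scenes in which it was valid.
    """

    band_q50: np.ndarray
    band_q25: np.ndarray
    band_q75: np.ndarray
    denominator: np.ndarray
    n_scenes: int
    grid: GridSpec
    tolerance: float = 0.05
    coverage_threshold: float = 0.5
    meta: dict = field(default_factory=dict)

    def bands(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (self.band_q50, self.band_q25, self.band_q75)


def scene_coverage(scene: Scene, geometry: LakeGeometry) -> float:
    """Fraction of the valid-water mask unflagged in this scene.

    A scene participates in the spatial statistics iff the fraction is at
    least the coverage threshold (inclusive, default 0.5).
    """
    if geometry.valid_water_mask is None:
        raise ValueError("geometry has no valid_water_mask; build it first")
    if not scene.grid.same_grid(geometry.grid):
        raise ValueError("scene and geometry are on different grids")
    n_water = int(geometry.valid_water_mask.sum())
    if n_water == 0:
        raise ValueError("valid-water mask is empty")
    valid = flg.valid_pixel_mask(scene.flags) & geometry.valid_water_mask
    return float(valid.sum()) / n_water


def lake_quantiles(values: Sequence[float]) -> tuple[float, float, float]:
    """(Q25, Q50, Q75) of a scene's valid chlorophyll values.

    Linear-interpolation quantiles; requires at least 4 values (scenes
    with fewer are skipped by the caller).
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 4:
        raise ValueError(f"need at least 4 valid values, got {vals.size}")
    q25, q50, q75 = np.quantile(vals, [0.25, 0.50, 0.75], method=QUANTILE_METHOD)
    return float(q25), float(q50), float(q75)


def summarize_scene(scene: Scene, geometry: LakeGeometry) -> QuantileSummary:
    """Coverage and quantiles of one scene over the valid-water mask."""
    cov = scene_coverage(scene, geometry)
    valid = flg.valid_pixel_mask(scene.flags) & geometry.valid_water_mask
    vals = scene.chl[valid]
    q25, q50, q75 = lake_quantiles(vals)
    return QuantileSummary(q25=q25, q50=q50, q75=q75,
                           n_valid=int(valid.sum()), coverage=cov)


def assign_quantile_bands(
    chl: np.ndarray,
    valid: np.ndarray,
    summary: QuantileSummary,
    tolerance: float = 0.05,
) -> dict[str, np.ndarray]:
    """Boolean rasters of pixels within +/-tolerance of each quantile.

    A valid pixel belongs to band q iff (1-tol)*q <= value <= (1+tol)*q,
    bounds inclusive. Bands are independent: a pixel may belong to several
    when the quantiles are close. A zero quantile degenerates to the
    zero-valued pixels (logged).
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    out = {}
    for key, q in zip(_BAND_KEYS, (summary.q50, summary.q25, summary.q75)):
        if q == 0:
            log.warning("quantile %s is 0; band degenerates to zero pixels", key)
        lo, hi = (1.0 - tolerance) * q, (1.0 + tolerance) * q
        with np.errstate(invalid="ignore"):
            out[key] = valid & (chl >= lo) & (chl <= hi)
    return out


def accumulate_frequencies(
    assignments: Sequence[dict[str, np.ndarray]],
    valid_masks: Sequence[np.ndarray],
    grid: GridSpec,
    tolerance: float = 0.05,
    coverage_threshold: float = 0.5,
    denominator: str = "per_pixel",
) -> CompositeFrequency:
    """Fold per-scene band assignments into a relative-frequency composite.

    ``denominator="per_pixel"`` divides each pixel's in-band count by the
    number of participating scenes in which that pixel was valid (pixels
    under recurrent cloud are not penalized); ``"scenes"`` divides by the
    total number of participating scenes. Pixels never valid get NaN.
    """
    if len(assignments) < 1:
        raise ValueError("need at least one participating scene")
    if len(assignments) != len(valid_masks):
        raise ValueError("assignments and valid_masks length mismatch")
    if denominator not in ("per_pixel", "scenes"):
        raise ValueError(f"unknown denominator rule: {denominator}")

    n_scenes = len(assignments)
    counts = {k: np.zeros(grid.shape, dtype=np.int64) for k in _BAND_KEYS}
    n_valid = np.zeros(grid.shape, dtype=np.int64)
    for bands, valid in zip(assignments, valid_masks):
        n_valid += valid.astype(np.int64)
        for k in _BAND_KEYS:
            counts[k] += bands[k].astype(np.int64)

    denom = n_valid if denominator == "per_pixel" else \
        np.full(grid.shape, n_scenes, dtype=np.int64)
    freq = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for k in _BAND_KEYS:
            f = 100.0 * counts[k] / denom
            f[n_valid == 0] = np.nan
            freq[k] = f
    return CompositeFrequency(
        band_q50=freq["q50"], band_q25=freq["q25"], band_q75=freq["q75"],
        denominator=n_valid, n_scenes=n_scenes, grid=grid,
        tolerance=tolerance, coverage_threshold=coverage_threshold,
        meta={"denominator_rule": denominator},
    )


def compute_composite(
    scenes: Sequence[Scene],
    geometry: LakeGeometry,
    tolerance: float = 0.05,
    coverage_threshold: float = 0.5,
    denominator: str = "per_pixel",
) -> CompositeFrequency:
    """End-to-end composite over a scene series.

    Applies the coverage rule, computes per-scene quantiles and band
    assignments, and accumulates frequencies. Scenes failing coverage or
    with fewer than 4 valid pixels are skipped with a log entry.
    """
    assignments, valid_masks = [], []
    for scene in scenes:
        cov = scene_coverage(scene, geometry)
        if cov < coverage_threshold:
            log.info("scene %s skipped: coverage %.2f < %.2f",
                     scene.timestamp, cov, coverage_threshold)
            continue
        valid = flg.valid_pixel_mask(scene.flags) & geometry.valid_water_mask
        try:
            q25, q50, q75 = lake_quantiles(scene.chl[valid])
        except ValueError:
            log.info("scene %s skipped: fewer than 4 valid values",
                     scene.timestamp)
            continue
        summary = QuantileSummary(q25=q25, q50=q50, q75=q75,
                                  n_valid=int(valid.sum()), coverage=cov)
        assignments.append(
            assign_quantile_bands(scene.chl, valid, summary, tolerance)
        )
        valid_masks.append(valid)
    if not assignments:
        raise ValueError("no scene passed the coverage rule")
    return accumulate_frequencies(
        assignments, valid_masks, geometry.grid,
        tolerance=tolerance, coverage_threshold=coverage_threshold,
        denominator=denominator,
    )
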