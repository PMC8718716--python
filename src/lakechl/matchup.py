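"""Satellite / in-situ match-up selection and macropixel quality control.

A candidate is an (in-situ sample, scene) pair whose acquisition times are
within a fixed window (default 24 h, inclusive). For each candidate the
3x3 macropixel (180 m x 180 m at 60 m resolution) centred on the station's
cell is extracted; the pair becomes a match-up when at least ``min_valid``
(default 6) of the nine pixels are valid and the valid values are
homogeneous — population standard deviation below 20% of their median.
The satellite value of a passing match-up is the arithmetic mean of the
valid macropixel values.

Failures are records with a ``rejection_reason``, never exceptions.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import flags as flg
from .grid import Scene

__all__ = [
    "InSituSample",
    "MatchupRecord",
    "pair_by_time",
    "extract_macropixel",
    "assess_homogeneity",
    "build_matchups",
]


@dataclass
class InSituSample:
    """A dated, georeferenced point chlorophyll measurement (mg m^-3)."""

    lake_id: str
    station_id: str
    x: float
    y: float
    timestamp: pd.Timestamp
    chl: float
    source: str = "monitoring"
    lat: Optional[float] = None
    lon: Optional[float] = None

    def __post_init__(self) -> None:
        self.timestamp = pd.Timestamp(self.timestamp)
        if self.timestamp.tzinfo is None:
            self.timestamp = self.timestamp.tz_localize("UTC")
        if not np.isfinite(self.chl) or self.chl <= 0:
            raise ValueError(f"in-situ chl must be > 0, got {self.chl}")


@dataclass
class MatchupRecord:
    """One QC'd candidate pair with full provenance.

    ``satellite_chl`` is defined only when ``passed``; ``macropixel_chl``
    holds the 3x3 values with NaN for invalid/out-of-raster cells.
    ``std_definition`` records the spread convention used ("population").
    """

    sample: InSituSample
    scene_timestamp: pd.Timestamp
    time_diff_hours: float
    n_valid: int = 0
    macropixel_chl: Optional[np.ndarray] = None
    satellite_chl: Optional[float] = None
    homogeneity_ratio: Optional[float] = None
    passed: bool = False
    rejection_reason: Optional[str] = None
    macropixel_iops: Optional[tuple[float, float, float]] = None
    std_definition: str = "population"
    meta: dict = field(default_factory=dict)


def pair_by_time(
    samples: Sequence[InSituSample],
    scenes: Sequence[Scene],
    window_hours: float = 24.0,
) -> list[tuple[InSituSample, Scene, float]]:
    """All (sample, scene, dt_hours) pairs with |dt| <= window (inclusive).

    A sample may pair with multiple scenes and vice versa.
    """
    pairs = []
    for sample in samples:
        for scene in scenes:
            dt_h = (sample.timestamp - scene.timestamp).total_seconds() / 3600.0
            if abs(dt_h) <= window_hours:
                pairs.append((sample, scene, dt_h))
    return pairs


def extract_macropixel(
    scene: Scene,
    x: float,
    y: float,
    valid_mask: np.ndarray,
    size: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """(values, validity) of the size x size block centred at point (x, y).

    The centre cell is the cell containing the point under the scene's
    affine transform; cells falling outside the raster are returned as NaN
    and invalid. Raises ``ValueError`` when the point itself is outside.
    """
    if size % 2 != 1 or size < 1:
        raise ValueError("macropixel size must be odd and >= 1")
    row, col = scene.grid.xy_to_index(x, y)  # raises outside raster
    half = size // 2
    values = np.full((size, size), np.nan)
    valid = np.zeros((size, size), dtype=bool)
    for i in range(size):
        for j in range(size):
            r, c = row - half + i, col - half + j
            if 0 <= r < scene.grid.rows and 0 <= c < scene.grid.cols:
                values[i, j] = scene.chl[r, c]
                valid[i, j] = bool(valid_mask[r, c]) and np.isfinite(scene.chl[r, c])
    return values, valid


def assess_homogeneity(values: Sequence[float], threshold: float = 0.20
                       ) -> tuple[float, bool]:
    """Spread ratio std/median of valid macropixel values and pass verdict.

    Population standard deviation (divide by n). Passes iff the ratio is
    strictly below ``threshold``. Raises ``ValueError`` on a non-positive
    median (callers convert that into a rejected record).
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 1:
        raise ValueError("need at least one valid value")
    med = float(np.median(vals))
    if med <= 0:
        raise ValueError("nonpositive_median")
    ratio = float(np.std(vals, ddof=0)) / med
    return ratio, ratio < threshold


def build_matchups(
    samples: Sequence[InSituSample],
    scenes: Sequence[Scene],
    window_hours: float = 24.0,
    min_valid: int = 6,
    homogeneity_threshold: float = 0.20,
    macropixel_size: int = 3,
) -> list[MatchupRecord]:
    """Run the full QC cascade over all in-window candidate pairs.

    Cascade order: time window (pairs outside it are not materialized) ->
    station inside raster -> n_valid >= min_valid -> homogeneity. The
    ``rejection_reason`` names the first failed criterion. Results do not
    depend on the ordering of samples or scenes.
    """
    records = []
    for sample, scene, dt_h in pair_by_time(samples, scenes, window_hours):
        rec = MatchupRecord(
            sample=sample,
            scene_timestamp=scene.timestamp,
            time_diff_hours=dt_h,
        )
        valid_mask = flg.valid_pixel_mask(scene.flags)
        try:
            values, valid = extract_macropixel(
                scene, sample.x, sample.y, valid_mask, size=macropixel_size
            )
        except ValueError:
            rec.rejection_reason = "outside_raster"
            records.append(rec)
            continue
        rec.macropixel_chl = np.where(valid, values, np.nan)
        rec.n_valid = int(valid.sum())
        if rec.n_valid < min_valid:
            rec.rejection_reason = "insufficient_valid"
            records.append(rec)
            continue
        good = values[valid]
        try:
            ratio, hom_ok = assess_homogeneity(good, homogeneity_threshold)
        except ValueError:
            rec.rejection_reason = "nonpositive_median"
            records.append(rec)
            continue
        rec.homogeneity_ratio = ratio
        if not hom_ok:
            rec.rejection_reason = "inhomogeneous"
            records.append(rec)
            continue
        rec.passed = True
        rec.satellite_chl = float(np.mean(good))
        if scene.has_iops:
            rec.macropixel_iops = tuple(
                float(np.nanmean(np.where(
                    valid, _block(arr, scene, sample, macropixel_size), np.nan)))
                for arr in (scene.a_pig, scene.a_det, scene.a_cdom)
            )
        records.append(rec)
    return records


def _block(arr: np.ndarray, scene: Scene, sample: InSituSample, size: int
           ) -> np.ndarray:
    """size x size window of ``arr`` centred on the sample's cell (NaN-padded)."""
    row, col = scene.grid.xy_to_index(sample.x, sample.y)
    half = size // 2
    out = np.full((size, size), np.nan)
    for i in range(size):
        for j in range(size):
            r, c = row - half + i, col - half + j
            if 0 <= r < scene.grid.rows and 0 <= c < scene.grid.cols:
                out[i, j] = arr[r, c]
    return out
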