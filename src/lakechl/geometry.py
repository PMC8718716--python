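"""Valid-water masking: shoreline buffer and shallow-water exclusion.

The usable part of a lake for optical retrievals excludes a strip along
the shore (mixed land-water pixels, adjacency effects) and areas shallow
enough for bottom reflectance to contaminate the signal. The shore strip
is removed by eroding the lake outline polygon inward by a fixed distance
(default 120 m); shallow areas are those whose bottom depth is less than
a high quantile (default 95%) of the transparency (Secchi depth) record.

Rasterization is by pixel-centre point-in-polygon. The quantile rule is
linear interpolation between order statistics; both choices are recorded
in mask metadata so results are auditable.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon
from shapely.geometry.base import BaseGeometry

from .grid import GridSpec

__all__ = [
    "LakeGeometry",
    "buffer_shoreline",
    "secchi_exclusion_depth",
    "rasterize_polygon",
    "build_valid_water_mask",
]

log = logging.getLogger(__name__)

QUANTILE_METHOD = "linear"


@dataclass
class LakeGeometry:
    """Lake outline, rasters, and the derived valid-water mask.

    ``bathymetry`` is depth in metres, positive down, 0 outside the lake.
    ``valid_water_mask`` is populated by :func:`build_valid_water_mask`.
    """

    lake_polygon: BaseGeometry
    grid: GridSpec
    lake_mask: np.ndarray
    bathymetry: np.ndarray
    buffer_distance: float = 120.0
    secchi_quantile: float = 0.95
    valid_water_mask: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.lake_mask.shape != self.grid.shape:
            raise ValueError("lake_mask shape does not match grid")
        if self.bathymetry.shape != self.grid.shape:
            raise ValueError("bathymetry shape does not match grid")
        if np.any(self.bathymetry < 0):
            raise ValueError("bathymetry must be >= 0 (depth, positive down)")
        if not (0 < self.secchi_quantile < 1):
            raise ValueError("secchi_quantile must be in (0, 1)")
        if self.buffer_distance < 0:
            raise ValueError("buffer_distance must be >= 0")


def buffer_shoreline(polygon: BaseGeometry, distance: float) -> BaseGeometry:
    """Erode a lake outline inward by ``distance`` metres.

    Returns the inward offset polygon; an empty geometry is a legitimate
    result for small lakes and is logged, not raised.
    """
    if distance < 0:
        raise ValueError(f"buffer distance must be >= 0, got {distance}")
    if polygon.is_empty:
        raise ValueError("cannot buffer an empty polygon")
    if not polygon.is_valid:
        raise ValueError("invalid polygon topology (self-intersection?)")
    if distance == 0:
        return polygon
    eroded = polygon.buffer(-distance)
    if eroded.is_empty:
        log.warning(
            "inward buffer of %.1f m erased the polygon (area %.1f m^2)",
            distance, polygon.area,
        )
    return eroded


def secchi_exclusion_depth(secchi_samples: Sequence[float], q: float = 0.95
                           ) -> float:
    """The q-quantile of the Secchi-depth record (metres).

    Linear-interpolation quantile over all pooled samples.
    """
    samples = np.asarray(secchi_samples, dtype=float)
    if samples.size == 0:
        raise ValueError("secchi_samples is empty")
    if not (0 < q < 1):
        raise ValueError(f"quantile must be in (0, 1), got {q}")
    if np.any(~np.isfinite(samples)) or np.any(samples <= 0):
        raise ValueError("Secchi depths must be finite and > 0")
    return float(np.quantile(samples, q, method=QUANTILE_METHOD))


def rasterize_polygon(polygon: BaseGeometry, grid: GridSpec) -> np.ndarray:
    """Boolean raster of pixels whose centre lies inside the polygon."""
    if polygon.is_empty:
        return np.zeros(grid.shape, dtype=bool)
    X, Y = grid.center_mesh()
    return shapely.contains_xy(polygon, X.ravel(), Y.ravel()).reshape(grid.shape)


def build_valid_water_mask(geometry: LakeGeometry,
                           secchi_samples: Sequence[float]) -> np.ndarray:
    """Build (and store) the valid-water mask for a lake.

    A pixel is valid water iff its centre lies inside the shoreline-buffered
    outline AND its bottom depth is at least the Secchi exclusion depth.
    The result doubles as the shoreline/shallow-water-buffer quality flag.
    """
    depth_cut = secchi_exclusion_depth(secchi_samples, geometry.secchi_quantile)
    buffered = buffer_shoreline(geometry.lake_polygon, geometry.buffer_distance)
    inside = rasterize_polygon(buffered, geometry.grid)
    deep_enough = geometry.bathymetry >= depth_cut
    mask = inside & deep_enough & geometry.lake_mask
    if not mask.any():
        log.warning(
            "valid-water mask is empty (buffer %.0f m, exclusion depth %.2f m, "
            "max bathymetry %.2f m)",
            geometry.buffer_distance, depth_cut, float(geometry.bathymetry.max()),
        )
    geometry.valid_water_mask = mask
    geometry.meta.update(
        {
            "secchi_exclusion_depth_m": depth_cut,
            "secchi_quantile": geometry.secchi_quantile,
            "quantile_method": QUANTILE_METHOD,
            "buffer_distance_m": geometry.buffer_distance,
            "rasterization": "pixel-centre point-in-polygon",
        }
    )
    return mask


def mask_to_polygon(mask: np.ndarray, grid: GridSpec) -> BaseGeometry:
    """Union of pixel squares for all True cells (for vector export)."""
    rows, cols = np.nonzero(mask)
    boxes = [
        shapely.box(
            grid.x0 + c * grid.cell_size,
            grid.y0 - (r + 1) * grid.cell_size,
            grid.x0 + (c + 1) * grid.cell_size,
            grid.y0 - r * grid.cell_size,
        )
        for r, c in zip(rows, cols)
    ]
    if not boxes:
        return Polygon()
    return shapely.unary_union(boxes)
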