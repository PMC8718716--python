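"""Raster grid georeference and the per-scene data container.

All geometry in this package lives on a projected, metre-based plane
(north-up, square pixels). The grid origin is the *outer corner* of the
top-left pixel; row indices increase southward (decreasing y), column
indices increase eastward (increasing x).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["GridSpec", "Scene"]


@dataclass(frozen=True)
class GridSpec:
    """Affine georeference of a north-up raster with square cells.

    Parameters
    ----------
    rows, cols
        Raster shape.
    cell_size
        Pixel edge length in metres (> 0).
    x0, y0
        Projected coordinates of the top-left *corner* of pixel (0, 0).
    crs
        Coordinate reference system identifier (informational).
    """

    rows: int
    cols: int
    cell_size: float = 60.0
    x0: float = 0.0
    y0: float = 0.0
    crs: str = "EPSG:2193"

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    def x_centers(self) -> np.ndarray:
        return self.x0 + (np.arange(self.cols) + 0.5) * self.cell_size

    def y_centers(self) -> np.ndarray:
        return self.y0 - (np.arange(self.rows) + 0.5) * self.cell_size

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of pixel-centre coordinates, shape (rows, cols)."""
        return np.meshgrid(self.x_centers(), self.y_centers())

    def xy_to_index(self, x: float, y: float) -> tuple[int, int]:
        """Grid indices of the cell containing projected point (x, y).

        Raises ``ValueError`` when the point falls outside the raster.
        """
        col = int(np.floor((x - self.x0) / self.cell_size))
        row = int(np.floor((self.y0 - y) / self.cell_size))
        if not (0 <= row < self.rows and 0 <= col < self.cols):
            raise ValueError(
                f"point ({x}, {y}) maps to cell ({row}, {col}) outside the "
                f"{self.rows}x{self.cols} raster"
            )
        return row, col

    def index_to_xy(self, row: int, col: int) -> tuple[float, float]:
        """Projected coordinates of the centre of cell (row, col)."""
        x = self.x0 + (col + 0.5) * self.cell_size
        y = self.y0 - (row + 0.5) * self.cell_size
        return x, y

    def same_grid(self, other: "GridSpec", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and abs(self.cell_size - other.cell_size) <= atol
            and abs(self.x0 - other.x0) <= atol
            and abs(self.y0 - other.y0) <= atol
        )


@dataclass
class Scene:
    """One dated raster snapshot of IOP fields, derived Chl and quality flags.

    ``chl`` and the IOP fields are NaN outside the lake; ``flags`` is an
    integer bitmask raster (see :mod:`lakechl.flags` for bit assignments).
    """

    timestamp: pd.Timestamp
    grid: GridSpec
    chl: np.ndarray
    flags: np.ndarray
    a_pig: Optional[np.ndarray] = None
    a_det: Optional[np.ndarray] = None
    a_cdom: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamp = pd.Timestamp(self.timestamp)
        if self.timestamp.tzinfo is None:
            self.timestamp = self.timestamp.tz_localize("UTC")
        for name in ("chl", "flags", "a_pig", "a_det", "a_cdom"):
            arr = getattr(self, name)
            if arr is not None and arr.shape != self.grid.shape:
                raise ValueError(
                    f"{name} shape {arr.shape} != grid shape {self.grid.shape}"
                )

    @property
    def has_iops(self) -> bool:
        return self.a_pig is not None and self.a_det is not None and self.a_cdom is not None
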