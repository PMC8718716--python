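"""Readers and writers for every artifact format.

* Scene time series: netCDF (classic format via the scipy backend), dims
  ``(time, y, x)``, variables ``chl``, ``a_pig``, ``a_det``, ``a_cdom``
  (float64, NaN-coded) and ``flags`` (int32 bitmask with CF
  ``flag_masks`` / ``flag_meanings`` attributes).
* In-situ samples: UTF-8 CSV with columns
  ``lake, station_id, x, y, lat, lon, datetime, chl_mg_m3, source``.
* Composites and bathymetry: GeoTIFF written through tifffile with
  ModelPixelScale/ModelTiepoint/GeoKey tags and a GDAL nodata tag.
* Polygons: GeoJSON.

All writers are deterministic given identical inputs.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import shapely
import tifffile
import xarray as xr
from shapely.geometry import mapping as shapely_mapping, shape as shapely_shape
from shapely.geometry.base import BaseGeometry

from . import flags as flg
from .grid import GridSpec, Scene
from .matchup import InSituSample, MatchupRecord
from .spatial_stats import BAND_NAMES, CompositeFrequency

__all__ = [
    "write_scene_series", "read_scene_series",
    "write_insitu_csv", "read_insitu_csv",
    "write_matchup_csv",
    "write_composite_geotiff", "read_composite_geotiff",
    "write_geotiff", "read_geotiff",
    "write_polygon_geojson", "read_polygon_geojson",
]

log = logging.getLogger(__name__)

INSITU_COLUMNS = ("lake", "station_id", "x", "y", "lat", "lon",
                  "datetime", "chl_mg_m3", "source")
_REQUIRED_INSITU = ("lake", "station_id", "x", "y", "datetime",
                    "chl_mg_m3", "source")

_TIME_ENCODING = {"units": "seconds since 1970-01-01T00:00:00",
                  "calendar": "proleptic_gregorian", "dtype": "float64"}


# ---------------------------------------------------------------- netCDF

def write_scene_series(scenes: Sequence[Scene], path) -> None:
    """Write a scene series to netCDF; lossless for chl, IOPs and flags."""
    if not scenes:
        raise ValueError("cannot write an empty scene series")
    grid = scenes[0].grid
    for s in scenes[1:]:
        if not s.grid.same_grid(grid):
            raise ValueError("scenes are on mixed grids")
    times = np.array(
        [s.timestamp.tz_convert("UTC").tz_localize(None).to_datetime64()
         for s in scenes]
    )
    if np.any(np.diff(times.astype("datetime64[ns]").astype(np.int64)) <= 0):
        raise ValueError("scene timestamps must be strictly increasing")

    def stack(name):
        arrs = [getattr(s, name) for s in scenes]
        if any(a is None for a in arrs):
            return None
        return np.stack(arrs)

    data_vars = {
        "chl": (("time", "y", "x"), stack("chl"),
                {"units": "mg m-3", "long_name": "chlorophyll a concentration"}),
        "flags": (("time", "y", "x"), stack("flags").astype(np.int32),
                  {"flag_masks": np.array([int(f) for f in flg.FLAG_ORDER],
                                          dtype=np.int32),
                   "flag_meanings": " ".join(f.name for f in flg.FLAG_ORDER)}),
    }
    for name in ("a_pig", "a_det", "a_cdom"):
        arr = stack(name)
        if arr is not None:
            data_vars[name] = (("time", "y", "x"), arr,
                               {"units": "m-1", "long_name": f"{name} absorption"})

    ds = xr.Dataset(
        data_vars=data_vars,
        coords={"time": times, "y": grid.y_centers(), "x": grid.x_centers()},
        attrs={
            "Conventions": "CF-1.8",
            "crs": grid.crs,
            "cell_size": grid.cell_size,
            "x0": grid.x0,
            "y0": grid.y0,
        },
    )
    ds.to_netcdf(path, engine="scipy", encoding={"time": _TIME_ENCODING})


def read_scene_series(path) -> list[Scene]:
    """Read a scene series written by :func:`write_scene_series`."""
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
    for required in ("chl", "flags"):
        if required not in ds:
            raise ValueError(f"scene series file lacks variable '{required}'")
    meanings = ds["flags"].attrs.get("flag_meanings", "")
    present = set(str(meanings).split())
    for f in flg.FLAG_ORDER:
        if f.name not in present:
            raise ValueError(f"flags variable is missing bit '{f.name}'")
    try:
        cell = float(ds.attrs["cell_size"])
        x0 = float(ds.attrs["x0"])
        y0 = float(ds.attrs["y0"])
    except KeyError as exc:
        raise ValueError(f"scene series file lacks grid attribute {exc}") from exc
    grid = GridSpec(rows=ds.sizes["y"], cols=ds.sizes["x"], cell_size=cell,
                    x0=x0, y0=y0, crs=str(ds.attrs.get("crs", "")))
    scenes = []
    for k in range(ds.sizes["time"]):
        ts = pd.Timestamp(ds["time"].values[k]).tz_localize("UTC")
        scenes.append(
            Scene(
                timestamp=ts,
                grid=grid,
                chl=ds["chl"].values[k],
                flags=ds["flags"].values[k].astype(np.int32),
                a_pig=ds["a_pig"].values[k] if "a_pig" in ds else None,
                a_det=ds["a_det"].values[k] if "a_det" in ds else None,
                a_cdom=ds["a_cdom"].values[k] if "a_cdom" in ds else None,
            )
        )
    return scenes


# ------------------------------------------------------------------- CSV

def write_insitu_csv(samples: Sequence[InSituSample], path) -> None:
    rows = [
        {
            "lake": s.lake_id,
            "station_id": s.station_id,
            "x": s.x,
            "y": s.y,
            "lat": s.lat if s.lat is not None else "",
            "lon": s.lon if s.lon is not None else "",
            "datetime": s.timestamp.isoformat(),
            "chl_mg_m3": s.chl,
            "source": s.source,
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=list(INSITU_COLUMNS)).to_csv(path, index=False)


def read_insitu_csv(path, column_map: Optional[dict] = None
                    ) -> list[InSituSample]:
    """Parse an in-situ CSV into samples.

    ``column_map`` renames foreign column names onto the canonical schema
    (``{"their_name": "chl_mg_m3", ...}``) so deposited files with other
    headers can be read. Timestamps must be ISO 8601 and are interpreted
    as UTC; a malformed date raises an error citing its line number; rows
    with missing chl or coordinates are skipped with a logged message.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    for col in _REQUIRED_INSITU:
        if col not in df.columns:
            raise ValueError(f"in-situ CSV is missing required column '{col}'")
    samples = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        if pd.isna(row["chl_mg_m3"]) or pd.isna(row["x"]) or pd.isna(row["y"]):
            log.warning("line %d: missing chl or coordinates; row skipped",
                        line_no)
            continue
        try:
            ts = pd.Timestamp(row["datetime"])
        except (ValueError, TypeError) as exc:
            raise ValueError(
                f"line {line_no}: malformed datetime {row['datetime']!r}"
            ) from exc
        if ts.tzinfo is None:
            ts = ts.tz_localize("UTC")
        samples.append(
            InSituSample(
                lake_id=str(row["lake"]),
                station_id=str(row["station_id"]),
                x=float(row["x"]),
                y=float(row["y"]),
                lat=None if "lat" not in row or pd.isna(row["lat"]) else float(row["lat"]),
                lon=None if "lon" not in row or pd.isna(row["lon"]) else float(row["lon"]),
                timestamp=ts,
                chl=float(row["chl_mg_m3"]),
                source=str(row["source"]),
            )
        )
    return samples


MATCHUP_COLUMNS = (
    "lake", "station_id", "sample_datetime", "scene_datetime",
    "time_diff_hours", "insitu_chl_mg_m3", "n_valid", "homogeneity_ratio",
    "std_definition", "satellite_chl_mg_m3", "a_pig", "a_det", "a_cdom",
    "passed", "rejection_reason",
)


def write_matchup_csv(records: Sequence[MatchupRecord], path) -> None:
    """Match-up table with all QC fields, one row per candidate."""
    rows = []
    for r in records:
        iops = r.macropixel_iops or (None, None, None)
        rows.append(
            {
                "lake": r.sample.lake_id,
                "station_id": r.sample.station_id,
                "sample_datetime": r.sample.timestamp.isoformat(),
                "scene_datetime": r.scene_timestamp.isoformat(),
                "time_diff_hours": r.time_diff_hours,
                "insitu_chl_mg_m3": r.sample.chl,
                "n_valid": r.n_valid,
                "homogeneity_ratio": r.homogeneity_ratio,
                "std_definition": r.std_definition,
                "satellite_chl_mg_m3": r.satellite_chl,
                "a_pig": iops[0],
                "a_det": iops[1],
                "a_cdom": iops[2],
                "passed": r.passed,
                "rejection_reason": r.rejection_reason or "",
            }
        )
    pd.DataFrame(rows, columns=list(MATCHUP_COLUMNS)).to_csv(path, index=False)


# --------------------------------------------------------------- GeoTIFF

_EPSG_FALLBACK = 32767  # "user-defined" per GeoTIFF spec


def _geo_extratags(grid: GridSpec) -> list:
    try:
        epsg = int(str(grid.crs).rsplit(":", 1)[-1])
    except ValueError:
        epsg = _EPSG_FALLBACK
    keys = (1, 1, 0, 3,
            1024, 0, 1, 1,      # model type: projected
            1025, 0, 1, 1,      # raster type: pixel-is-area
            3072, 0, 1, epsg)   # projected CRS code
    return [
        (33550, "d", 3, (grid.cell_size, grid.cell_size, 0.0), True),
        (33922, "d", 6, (0.0, 0.0, 0.0, grid.x0, grid.y0, 0.0), True),
        (34735, "H", len(keys), keys, True),
        (42113, "s", 0, "nan", True),
    ]


def write_geotiff(bands: np.ndarray, grid: GridSpec, path,
                  band_names: Sequence[str], metadata: Optional[dict] = None
                  ) -> None:
    """Write (n_bands, rows, cols) float data as a georeferenced TIFF."""
    bands = np.asarray(bands, dtype=np.float64)
    if bands.ndim == 2:
        bands = bands[None]
    if bands.shape[1:] != grid.shape:
        raise ValueError("band shape does not match grid")
    if len(band_names) != bands.shape[0]:
        raise ValueError("need one band name per band")
    desc = json.dumps(
        {
            "band_names": list(band_names),
            "nodata": "nan",
            "crs": grid.crs,
            "cell_size": grid.cell_size,
            "x0": grid.x0,
            "y0": grid.y0,
            **(metadata or {}),
        },
        sort_keys=True,
    )
    tifffile.imwrite(
        path, bands, photometric="minisblack", metadata=None,
        description=desc, extratags=_geo_extratags(grid),
    )


def read_geotiff(path) -> tuple[np.ndarray, GridSpec, dict]:
    """(bands, grid, metadata) of a TIFF written by :func:`write_geotiff`."""
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        page = tif.pages[0]
        desc = page.description
    meta = json.loads(desc)
    if data.ndim == 2:
        data = data[None]
    grid = GridSpec(rows=data.shape[1], cols=data.shape[2],
                    cell_size=float(meta["cell_size"]),
                    x0=float(meta["x0"]), y0=float(meta["y0"]),
                    crs=str(meta["crs"]))
    return data, grid, meta


def write_composite_geotiff(composite: CompositeFrequency, path) -> None:
    """3-band composite: near-median / near-lower / near-upper quartile."""
    bands = np.stack(composite.bands())
    write_geotiff(
        bands, composite.grid, path, band_names=list(BAND_NAMES),
        metadata={
            "tolerance": composite.tolerance,
            "coverage_threshold": composite.coverage_threshold,
            "n_scenes": composite.n_scenes,
            **composite.meta,
        },
    )


def read_composite_geotiff(path) -> CompositeFrequency:
    data, grid, meta = read_geotiff(path)
    if data.shape[0] != 3:
        raise ValueError(f"composite GeoTIFF must have 3 bands, found {data.shape[0]}")
    return CompositeFrequency(
        band_q50=data[0], band_q25=data[1], band_q75=data[2],
        denominator=np.zeros(grid.shape, dtype=np.int64),
        n_scenes=int(meta.get("n_scenes", 0)), grid=grid,
        tolerance=float(meta.get("tolerance", 0.05)),
        coverage_threshold=float(meta.get("coverage_threshold", 0.5)),
        meta={k: meta[k] for k in meta if k not in
              ("band_names", "nodata", "crs", "cell_size", "x0", "y0")},
    )


# --------------------------------------------------------------- GeoJSON

def write_polygon_geojson(polygon: BaseGeometry, path,
                          properties: Optional[dict] = None) -> None:
    feature = {
        "type": "Feature",
        "geometry": shapely_mapping(polygon),
        "properties": properties or {},
    }
    collection = {"type": "FeatureCollection", "features": [feature]}
    Path(path).write_text(json.dumps(collection, sort_keys=True))


def read_polygon_geojson(path) -> tuple[BaseGeometry, dict]:
    doc = json.loads(Path(path).read_text())
    feats = doc.get("features", [])
    if not feats:
        raise ValueError("GeoJSON file contains no features")
    geom = shapely_shape(feats[0]["geometry"])
    if not geom.is_valid:
        geom = shapely.make_valid(geom)
    return geom, feats[0].get("properties", {})
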