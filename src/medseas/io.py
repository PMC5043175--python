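"""File I/O: NetCDF grids, CSV tables and GeoJSON geometries.

NetCDF files are written through xarray's scipy backend (classic NetCDF3),
which keeps the on-disk format plain and dependency-light.  GeoJSON is
written as plain JSON feature collections.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import xarray as xr
from shapely.geometry import mapping


def write_netcdf(ds: xr.Dataset, path: str | Path) -> None:
    ds.to_netcdf(path, engine="scipy")


def read_netcdf(path: str | Path) -> xr.Dataset:
    with xr.open_dataset(path, engine="scipy") as ds:
        return ds.load()


def write_geojson(features: list[dict], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )


def read_geojson(path: str | Path) -> list[dict]:
    return json.loads(Path(path).read_text())["features"]


def polygon_feature(geom, properties: dict) -> dict:
    """GeoJSON feature from a shapely geometry."""
    return {"type": "Feature", "geometry": mapping(geom), "properties": properties}


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
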