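"""File formats: CSV tables, GeoJSON polylines/polygons, local metric <-> lon/lat.

All pipeline tables are UTF-8 comma-separated CSV with a header row.
Polylines (shoreline, wave break) and polygons (KDE contours, footprints)
are GeoJSON.  Geographic coordinates are converted to the per-beach local
metric frame by equirectangular scaling about the beach centroid: at the
scale of a single beach (a few km) the error of this projection is far
below the survey's distance resolution.
"""

from __future__ import annotations

import json
import math

import numpy as np
import pandas as pd

EARTH_RADIUS_M = 6_371_000.0

__all__ = [
    "lonlat_to_local",
    "local_to_lonlat",
    "write_linestring_geojson",
    "read_linestring_geojson",
    "write_polygons_geojson",
]


def lonlat_to_local(lon, lat, lon0: float, lat0: float) -> tuple[np.ndarray, np.ndarray]:
    """Equirectangular projection about (lon0, lat0), metres east/north."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    x = np.radians(lon - lon0) * EARTH_RADIUS_M * math.cos(math.radians(lat0))
    y = np.radians(lat - lat0) * EARTH_RADIUS_M
    return x, y


def local_to_lonlat(x, y, lon0: float, lat0: float) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lon = lon0 + np.degrees(x / (EARTH_RADIUS_M * math.cos(math.radians(lat0))))
    lat = lat0 + np.degrees(y / EARTH_RADIUS_M)
    return lon, lat


def write_linestring_geojson(path, vertices: np.ndarray, properties: dict | None = None) -> None:
    feature = {
        "type": "Feature",
        "properties": properties or {},
        "geometry": {"type": "LineString",
                     "coordinates": [[float(x), float(y)] for x, y in vertices]},
    }
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": [feature]}, fh, indent=1)


def read_linestring_geojson(path) -> tuple[np.ndarray, dict]:
    with open(path) as fh:
        data = json.load(fh)
    if data.get("type") == "FeatureCollection":
        feature = data["features"][0]
    elif data.get("type") == "Feature":
        feature = data
    else:
        feature = {"geometry": data, "properties": {}}
    geom = feature["geometry"]
    if geom["type"] != "LineString":
        raise ValueError(f"expected LineString, got {geom['type']}")
    return np.asarray(geom["coordinates"], dtype=float), feature.get("properties", {})


def write_polygons_geojson(path, polygons: list[tuple[np.ndarray, dict]]) -> None:
    """Write [(ring_vertices, properties), ...] as a polygon FeatureCollection."""
    features = []
    for ring, props in polygons:
        coords = [[float(x), float(y)] for x, y in ring]
        if coords and coords[0] != coords[-1]:
            coords.append(coords[0])
        features.append({"type": "Feature", "properties": props,
                         "geometry": {"type": "Polygon", "coordinates": [coords]}})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)


def write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.6f")


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
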