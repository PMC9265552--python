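"""Format adapters: GeoJSON vectors, ESRI ASCII rasters, CSV tables.

All geometry must already be in one projected CRS in meters; geographic
(lon/lat) coordinates are rejected rather than silently reprojected,
because every bandwidth in the pipeline is metric.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .grids import Surface

__all__ = [
    "write_points_geojson",
    "read_points_geojson",
    "write_polygons_geojson",
    "read_polygons_geojson",
    "write_cases_csv",
    "read_cases_csv",
    "write_surface",
    "read_surface",
]


def _looks_geographic(coords: np.ndarray) -> bool:
    return bool(
        np.all(np.abs(coords[:, 0]) <= 360) and np.all(np.abs(coords[:, 1]) <= 90)
    )


def _check_projected(coords: np.ndarray) -> None:
    if len(coords) and _looks_geographic(coords):
        raise ValueError(
            "coordinates look geographic (lon/lat); reproject to a metric CRS first"
        )


def write_points_geojson(path, ids, points, properties: pd.DataFrame | None = None) -> None:
    pts = np.asarray(points, dtype=float)
    features = []
    for i, (vid, (x, y)) in enumerate(zip(ids, pts)):
        props = {"village_id": vid}
        if properties is not None:
            props.update(
                {k: _jsonable(v) for k, v in properties.iloc[i].to_dict().items()}
            )
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
                "properties": props,
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v


def read_points_geojson(path):
    """Returns (ids, (n,2) coords, properties DataFrame)."""
    data = json.loads(Path(path).read_text())
    ids, coords, props = [], [], []
    for feat in data["features"]:
        geom = feat["geometry"]
        if geom["type"] != "Point":
            raise ValueError(f"expected Point features, got {geom['type']}")
        coords.append(geom["coordinates"][:2])
        p = dict(feat.get("properties") or {})
        ids.append(p.pop("village_id", len(ids)))
        props.append(p)
    coords = np.asarray(coords, dtype=float)
    _check_projected(coords)
    return ids, coords, pd.DataFrame(props, index=ids)


def write_polygons_geojson(path, polygons: dict) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(geom),
            "properties": {"village_id": vid},
        }
        for vid, geom in polygons.items()
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def read_polygons_geojson(path) -> dict:
    data = json.loads(Path(path).read_text())
    out = {}
    for feat in data["features"]:
        vid = (feat.get("properties") or {}).get("village_id", len(out))
        out[vid] = shape(feat["geometry"])
    return out


def write_cases_csv(path, cases: pd.DataFrame) -> None:
    cases.to_csv(path, index=False)


def read_cases_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"village_id", "stratum", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"case table at {path} missing columns {sorted(missing)}")
    return df


def write_surface(path, surface: Surface) -> None:
    surface.write_ascii(path)


def read_surface(path) -> Surface:
    return Surface.read_ascii(path)
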