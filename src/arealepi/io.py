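"""Areal-layer and provider I/O.

Area layers are GeoJSON FeatureCollections carrying one polygon feature
per administrative unit with its attribute table in the feature
properties.  All spatial analysis in this package assumes a metric
(projected, meters) coordinate system; layers delivered in geographic
longitude/latitude can be reprojected on read with a built-in WGS84
UTM forward projection (``crs_policy="auto_utm"``).

Weights are exchanged in a plain adjacency-list text format (first line
the unit count, then ``id n_neighbors nbr1 nbr2 ...`` per unit) for
cross-checks against other tools.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.ops import transform as shp_transform

from .weights import SpatialWeights

__all__ = [
    "read_area_layer",
    "write_area_layer",
    "read_providers",
    "write_providers",
    "read_weights",
    "write_weights",
    "utm_forward",
]

_METRIC_CRS_NAME = "urn:arealepi:metric"

# WGS84 ellipsoid
_A = 6378137.0
_F = 1.0 / 298.257223563
_E2 = _F * (2.0 - _F)
_EP2 = _E2 / (1.0 - _E2)
_K0 = 0.9996


def utm_forward(lon: float, lat: float, zone: int | None = None) -> tuple[float, float]:
    """WGS84 geographic -> UTM easting/northing (meters).

    Standard transverse-Mercator series on the WGS84 ellipsoid; zone
    derived from longitude unless given.  Southern-hemisphere points get
    the 10,000 km false northing.
    """
    if zone is None:
        zone = int(lon // 6) + 31
    lam0 = math.radians((zone - 1) * 6 - 180 + 3)
    phi = math.radians(lat)
    lam = math.radians(lon)
    sin_p, cos_p, tan_p = math.sin(phi), math.cos(phi), math.tan(phi)
    N = _A / math.sqrt(1 - _E2 * sin_p**2)
    T = tan_p**2
    C = _EP2 * cos_p**2
    Aq = (lam - lam0) * cos_p
    e2, e4, e6 = _E2, _E2**2, _E2**3
    M = _A * (
        (1 - e2 / 4 - 3 * e4 / 64 - 5 * e6 / 256) * phi
        - (3 * e2 / 8 + 3 * e4 / 32 + 45 * e6 / 1024) * math.sin(2 * phi)
        + (15 * e4 / 256 + 45 * e6 / 1024) * math.sin(4 * phi)
        - (35 * e6 / 3072) * math.sin(6 * phi)
    )
    x = 500000.0 + _K0 * N * (
        Aq
        + (1 - T + C) * Aq**3 / 6
        + (5 - 18 * T + T**2 + 72 * C - 58 * _EP2) * Aq**5 / 120
    )
    y = _K0 * (
        M
        + N * tan_p
        * (
            Aq**2 / 2
            + (5 - T + 9 * C + 4 * C**2) * Aq**4 / 24
            + (61 - 58 * T + T**2 + 600 * C - 330 * _EP2) * Aq**6 / 720
        )
    )
    if lat < 0:
        y += 10_000_000.0
    return x, y


def _looks_geographic(geoms) -> bool:
    xs, ys = [], []
    for g in geoms:
        x0, y0, x1, y1 = g.bounds
        xs += [x0, x1]
        ys += [y0, y1]
    return max(map(abs, xs)) <= 180.0 and max(map(abs, ys)) <= 90.0


def read_area_layer(path, id_field: str = "unit_id",
                    crs_policy: str = "require_metric") -> pd.DataFrame:
    """Read a GeoJSON polygon layer into an area table.

    ``crs_policy``: "require_metric" errors on geographic (degree)
    coordinates; "auto_utm" reprojects degrees to the UTM zone of the
    layer's mean longitude; "none" takes coordinates as given.  Row order
    is preserved.
    """
    if crs_policy not in ("require_metric", "auto_utm", "none"):
        raise ValueError(f"unknown crs_policy {crs_policy!r}")
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    rows = []
    for feat in gj["features"]:
        props = dict(feat.get("properties") or {})
        if id_field not in props:
            raise ValueError(f"{path}: feature missing id field {id_field!r}")
        props["unit_id"] = props.pop(id_field)
        props["geometry"] = shape(feat["geometry"])
        rows.append(props)
    df = pd.DataFrame(rows)
    dup = df["unit_id"][df["unit_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate unit_id {dup.iloc[0]!r}")

    declared_metric = gj.get("crs", {}).get("properties", {}).get("name") == _METRIC_CRS_NAME
    geographic = (not declared_metric) and _looks_geographic(df["geometry"])
    if geographic:
        if crs_policy == "require_metric":
            raise ValueError(
                f"{path}: coordinates look geographic (degrees) but a metric "
                "CRS is required; use crs_policy='auto_utm'"
            )
        if crs_policy == "auto_utm":
            mean_lon = float(np.mean([g.centroid.x for g in df["geometry"]]))
            zone = int(mean_lon // 6) + 31
            proj = lambda x, y: utm_forward(x, y, zone=zone)
            df["geometry"] = [shp_transform(proj, g) for g in df["geometry"]]
    return df


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_area_layer(df: pd.DataFrame, path, metric: bool = True) -> None:
    """Write an area table (attributes + polygons) as GeoJSON."""
    feats = []
    attr_cols = [c for c in df.columns if c != "geometry"]
    for _, row in df.iterrows():
        feats.append(
            {
                "type": "Feature",
                "properties": {c: row[c] for c in attr_cols},
                "geometry": mapping(row["geometry"]),
            }
        )
    gj: dict = {"type": "FeatureCollection", "features": feats}
    if metric:
        gj["crs"] = {"type": "name", "properties": {"name": _METRIC_CRS_NAME}}
    with open(path, "w") as fh:
        json.dump(gj, fh, default=_json_default)
        fh.write("\n")


def read_providers(path) -> pd.DataFrame:
    """Provider points from CSV (provider_id,x,y,capacity) or point GeoJSON."""
    path = Path(path)
    if path.suffix.lower() in (".geojson", ".json"):
        with open(path) as fh:
            gj = json.load(fh)
        rows = []
        for feat in gj["features"]:
            props = dict(feat.get("properties") or {})
            geom = shape(feat["geometry"])
            props.setdefault("capacity", 1)
            props["x"], props["y"] = geom.x, geom.y
            rows.append(props)
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(path)
    required = {"provider_id", "x", "y", "capacity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: provider table missing columns {sorted(missing)}")
    if df["provider_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate provider ids")
    return df


def write_providers(df: pd.DataFrame, path) -> None:
    cols = [c for c in df.columns if c != "geometry"]
    df[cols].to_csv(path, index=False)


def write_weights(w: SpatialWeights, path) -> None:
    with open(path, "w") as fh:
        fh.write(w.to_adjlist_text())


def read_weights(path, mode: str = "binary") -> SpatialWeights:
    with open(path) as fh:
        return SpatialWeights.from_adjlist_text(fh.read(), mode=mode)
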