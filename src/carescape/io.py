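"""Readers and writers for the package's interchange formats.

Point layers travel as GeoJSON FeatureCollections (point geometry,
attributes as properties); tables as headered CSV with Likert codes 1-5,
walking-time codes 1-3, and missing prices as empty fields.  The study
region is an abstract planar unit square, so no CRS is attached.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .access import DemandPoint, SupplyPoint
from .errors import ValidationError
from .layout import PointPattern


def _feature(x: float, y: float, properties: dict) -> dict:
    return {
        "type": "Feature",
        "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
        "properties": properties,
    }


def write_point_geojson(path, xs, ys, properties: list[dict]) -> None:
    features = [_feature(x, y, p) for x, y, p in zip(xs, ys, properties)]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)


def read_point_geojson(path) -> pd.DataFrame:
    """Flatten a point FeatureCollection to a DataFrame with x, y columns."""
    with open(path) as fh:
        data = json.load(fh)
    if data.get("type") != "FeatureCollection":
        raise ValidationError(f"{path}: not a GeoJSON FeatureCollection")
    rows = []
    for feat in data.get("features", []):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point":
            raise ValidationError(f"{path}: only Point geometry is supported")
        x, y = geom["coordinates"][:2]
        rows.append({"x": x, "y": y, **(feat.get("properties") or {})})
    return pd.DataFrame(rows)


def write_communities(path, communities: pd.DataFrame) -> None:
    props = communities.drop(columns=["x", "y"]).to_dict("records")
    write_point_geojson(path, communities["x"], communities["y"], props)


def write_facilities(path, pattern: PointPattern, capacities) -> None:
    labels = pattern.labels or [f"F{i + 1:02d}" for i in range(pattern.n)]
    props = [
        {"facility_id": lab, "capacity": float(c)}
        for lab, c in zip(labels, capacities)
    ]
    write_point_geojson(path, pattern.points[:, 0], pattern.points[:, 1], props)


def read_facilities(path, region_area: float = 1.0):
    df = read_point_geojson(path)
    pattern = PointPattern(
        points=df[["x", "y"]].to_numpy(float),
        region_area=region_area,
        labels=list(df.get("facility_id", df.index.astype(str))),
    )
    capacities = df.get("capacity", pd.Series(np.ones(len(df)))).to_numpy(float)
    return pattern, capacities


def read_supply_points(path) -> list[SupplyPoint]:
    df = read_point_geojson(path)
    ids = df.get("facility_id", df.index.astype(str))
    caps = df.get("capacity", pd.Series(np.ones(len(df))))
    return [
        SupplyPoint(id=str(i), location=(row.x, row.y), capacity=float(c))
        for i, c, row in zip(ids, caps, df.itertuples())
    ]


def read_demand_points(path, demand_field: str = "older_population") -> list[DemandPoint]:
    df = read_point_geojson(path)
    ids = df.get("community_id", df.index.astype(str))
    if demand_field not in df.columns:
        raise ValidationError(f"{path}: missing demand field {demand_field!r}")
    return [
        DemandPoint(id=str(i), location=(row.x, row.y), demand=float(d))
        for i, d, row in zip(ids, df[demand_field], df.itertuples())
    ]


def write_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_survey(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_od_matrix(path, supplies: list[SupplyPoint],
                   demands: list[DemandPoint]) -> np.ndarray:
    """Long-format `demand_id,supply_id,distance` CSV to a dense matrix."""
    df = pd.read_csv(path)
    required = {"demand_id", "supply_id", "distance"}
    if not required <= set(df.columns):
        raise ValidationError(f"{path}: OD matrix needs columns {sorted(required)}")
    di = {d.id: i for i, d in enumerate(demands)}
    sj = {s.id: j for j, s in enumerate(supplies)}
    out = np.full((len(demands), len(supplies)), np.nan)
    for rec in df.itertuples():
        out[di[str(rec.demand_id)], sj[str(rec.supply_id)]] = rec.distance
    if np.isnan(out).any():
        raise ValidationError(f"{path}: OD matrix has missing pairs")
    return out
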