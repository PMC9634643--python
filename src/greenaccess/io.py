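"""Readers and writers for the pipeline's plain-text artifacts.

Tabular artifacts are CSV with fixed column orders; geometries go to
GeoJSON with 6-decimal coordinate precision; mode shares, truth and the
run manifest are JSON.  All readers validate schemas and report the
offending file, line and column on failure.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from shapely.geometry import mapping, shape

from greenaccess.grid import HexGrid, Park, SupplyPoint
from greenaccess.signaling import EVENT_COLUMNS, ModeShares

__all__ = [
    "read_events", "write_events",
    "read_od", "write_od",
    "read_surface", "write_surface",
    "write_cells_geojson", "write_parks_geojson", "read_parks_geojson",
    "write_supply_points", "read_supply_points",
    "write_mode_shares", "read_mode_shares",
    "write_json", "read_json",
]


class SchemaError(ValueError):
    """A file does not conform to its declared schema."""


def _round_coords(obj, nd: int = 6):
    if isinstance(obj, (list, tuple)):
        return [_round_coords(o, nd) for o in obj]
    if isinstance(obj, float):
        return round(obj, nd)
    return obj


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def read_events(path) -> pd.DataFrame:
    """events.csv: user_id, t_start, t_end, cell_id (ISO-8601 timestamps)."""
    df = pd.read_csv(path, dtype={"user_id": str})
    _require_columns(df, EVENT_COLUMNS, path)
    try:
        df["t_start"] = pd.to_datetime(df["t_start"], format="ISO8601")
        df["t_end"] = pd.to_datetime(df["t_end"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"{path}: unparseable timestamp ({exc})") from exc
    bad = df.index[df["t_end"] < df["t_start"]]
    if len(bad):
        raise SchemaError(f"{path}: line {bad[0] + 2}, column t_end: interval ends before it starts")
    df["cell_id"] = df["cell_id"].astype(int)
    return df[EVENT_COLUMNS]


def write_events(events: pd.DataFrame, path) -> None:
    out = events[EVENT_COLUMNS].copy()
    out["t_start"] = pd.to_datetime(out["t_start"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out["t_end"] = pd.to_datetime(out["t_end"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_od(path) -> pd.DataFrame:
    """od_<mode>.csv: supply_id, cell_id, distance_m; distances must be ≥ 0."""
    df = pd.read_csv(path)
    _require_columns(df, ["supply_id", "cell_id", "distance_m"], path)
    neg = df.index[df["distance_m"] < 0]
    if len(neg):
        raise SchemaError(f"{path}: line {neg[0] + 2}, column distance_m: negative distance")
    return df


def write_od(od_table: pd.DataFrame, path) -> None:
    od_table.to_csv(path, index=False, float_format="%.3f")


def read_surface(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["cell_id"], path)
    return df.set_index("cell_id")


def write_surface(surface: pd.DataFrame, path) -> None:
    surface.to_csv(path, index=True, float_format="%.10g")


def write_cells_geojson(grid: HexGrid, path, extra: pd.DataFrame | None = None) -> None:
    """Cell polygons with population/role properties, optionally joined with
    per-cell analysis columns (accessibility, grade, Z, ...)."""
    feats = []
    for c in grid.cells:
        props = {
            "cell_id": c.cell_id,
            "population": int(c.population),
            "visitors": int(c.visitors),
            "is_residential": bool(c.is_residential),
            "is_ugs": bool(c.is_ugs),
        }
        if extra is not None and c.cell_id in extra.index:
            for k, v in extra.loc[c.cell_id].items():
                props[k] = None if pd.isna(v) else (v.item() if hasattr(v, "item") else v)
        feats.append({
            "type": "Feature",
            "geometry": _round_coords(mapping(c.polygon)),
            "properties": props,
        })
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


def write_parks_geojson(parks: Iterable[Park], path) -> None:
    feats = [{
        "type": "Feature",
        "geometry": _round_coords(mapping(p.polygon)),
        "properties": {
            "park_id": p.park_id,
            "name": p.name,
            "area_hm2": round(p.area, 6),
            "category": p.category,
            "entrances": _round_coords([list(e) for e in p.entrances]),
        },
    } for p in parks]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


def read_parks_geojson(path) -> list[Park]:
    data = json.loads(Path(path).read_text())
    parks = []
    for feat in data.get("features", []):
        props = feat.get("properties", {})
        try:
            parks.append(Park(
                park_id=int(props["park_id"]),
                name=str(props.get("name", "")),
                polygon=shape(feat["geometry"]),
                area=float(props["area_hm2"]),
                entrances=[tuple(e) for e in props.get("entrances", [])],
                category=str(props.get("category", "community")),
            ))
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"{path}: park feature missing {exc}") from exc
    return parks


def write_supply_points(points: Iterable[SupplyPoint], path) -> None:
    rows = [(p.supply_id, p.park_id, p.location[0], p.location[1], p.supply_scale) for p in points]
    pd.DataFrame(rows, columns=["supply_id", "park_id", "x", "y", "supply_scale"]).to_csv(
        path, index=False, float_format="%.6f")


def read_supply_points(path) -> list[SupplyPoint]:
    df = pd.read_csv(path)
    _require_columns(df, ["supply_id", "park_id", "x", "y", "supply_scale"], path)
    bad = df.index[df["supply_scale"] <= 0]
    if len(bad):
        raise SchemaError(f"{path}: line {bad[0] + 2}, column supply_scale: must be positive")
    return [SupplyPoint(int(r.supply_id), int(r.park_id), (float(r.x), float(r.y)), float(r.supply_scale))
            for r in df.itertuples()]


def write_mode_shares(shares: ModeShares, path) -> None:
    Path(path).write_text(json.dumps(shares.as_dict(), indent=2, sort_keys=True))


def read_mode_shares(path) -> ModeShares:
    d = json.loads(Path(path).read_text())
    return ModeShares(**{k: float(d[k]) for k in ("walking", "cycling", "driving")})


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


def read_json(path):
    return json.loads(Path(path).read_text())
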