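"""Readers, validators and writers for the three input data families.

Supported on-disk formats:

* building damage polygons — GeoJSON or GeoPackage (``.gpkg``), one feature
  per building with a numeric damaged-fraction attribute;
* building damage centroids — GeoJSON points or CSV with lon/lat (or x/y)
  columns and a binary class column (optionally a score column plus a
  threshold);
* health facilities — CSV with columns
  ``facility_id,name,ftype,city,lon,lat[,gold_label]`` or GeoJSON points with
  the same properties; an XLSX dialect with a user-supplied column mapping is
  also accepted for per-facility summary tables.

GeoPackage support is a minimal read-only implementation: a GeoPackage is an
SQLite database whose geometry blobs are ISO WKB behind a small binary
header, so the standard-library ``sqlite3`` module plus shapely's WKB reader
cover everything needed here.

Every record read is either returned or logged as rejected with a reason;
callers that need the reconciliation can pass a ``rejects`` list.
"""

from __future__ import annotations

import csv
import json
import logging
import math
import re
import sqlite3
import struct
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from shapely import wkb as shapely_wkb
from shapely.geometry import Point, mapping, shape
from shapely.validation import make_valid

from .projection import LocalProjection, looks_geographic
from .types import (
    DamageCentroid,
    DamagePolygon,
    FacilityType,
    HealthFacility,
)

log = logging.getLogger(__name__)

__all__ = [
    "read_damage_polygons",
    "read_damage_centroids",
    "read_facilities",
    "read_facility_table_xlsx",
    "deduplicate_facilities",
    "to_metric",
    "normalize_name",
    "write_facilities_csv",
    "write_calls_csv",
    "write_geojson",
]


# ---------------------------------------------------------------------------
# low-level feature readers


def _read_geojson_features(path: Path) -> list[dict]:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") == "FeatureCollection":
        return doc.get("features", [])
    if doc.get("type") == "Feature":
        return [doc]
    raise ValueError(f"{path}: not a GeoJSON Feature or FeatureCollection")


def _read_gpkg_features(path: Path, layer: Optional[str] = None) -> list[dict]:
    """Read one vector layer of a GeoPackage as GeoJSON-like feature dicts."""
    con = sqlite3.connect(path)
    try:
        rows = con.execute(
            "SELECT table_name, column_name FROM gpkg_geometry_columns"
        ).fetchall()
        if not rows:
            raise ValueError(f"{path}: no vector layers in gpkg_geometry_columns")
        tables = {t: c for t, c in rows}
        if layer is None:
            if len(tables) > 1:
                raise ValueError(
                    f"{path}: multiple layers {sorted(tables)}; specify one"
                )
            layer = next(iter(tables))
        if layer not in tables:
            raise ValueError(f"{path}: no layer named {layer!r}")
        geom_col = tables[layer]
        cur = con.execute(f'SELECT * FROM "{layer}"')  # noqa: S608 - layer vetted above
        names = [d[0] for d in cur.description]
        gi = names.index(geom_col)
        features = []
        for row in cur:
            geom = _parse_gpkg_geometry(row[gi])
            props = {n: v for i, (n, v) in enumerate(zip(names, row)) if i != gi}
            features.append(
                {"type": "Feature", "geometry": geom, "properties": props, "_shape": geom}
            )
        return features
    finally:
        con.close()


def _parse_gpkg_geometry(blob: Optional[bytes]):
    """GeoPackage geometry blob -> shapely geometry (or None)."""
    if blob is None:
        return None
    if blob[:2] != b"GP":
        raise ValueError("not a GeoPackage geometry blob")
    flags = blob[3]
    envelope_code = (flags >> 1) & 0b111
    envelope_len = {0: 0, 1: 32, 2: 48, 3: 48, 4: 64}[envelope_code]
    return shapely_wkb.loads(blob[8 + envelope_len :])


def _features(path: str | Path, layer: Optional[str] = None) -> list[dict]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".gpkg":
        return _read_gpkg_features(path, layer)
    return _read_geojson_features(path)


def _geom_of(feature: dict):
    g = feature.get("_shape")
    if g is not None:
        return g
    geom = feature.get("geometry")
    return shape(geom) if geom else None


# ---------------------------------------------------------------------------
# damage polygons


def read_damage_polygons(
    path: str | Path,
    damage_field: str = "damage_fraction",
    layer: Optional[str] = None,
    proj: Optional[LocalProjection] = None,
    crs: str = "auto",
    rejects: Optional[list] = None,
) -> list[DamagePolygon]:
    """Read polygon-dialect model output.

    Damage values with a maximum above 1.5 are treated as percentages and
    divided by 100 (the two conventions are otherwise indistinguishable; the
    normalization is logged). Invalid geometries are repaired where possible;
    multipolygons are split into parts, each keeping the parent's fraction
    with the id suffixed ``::0``, ``::1``, ...

    If coordinates are geographic, they are reprojected with ``proj`` (fitted
    to the data centroid when not supplied). ``crs`` declares the input
    coordinate kind: ``"geographic"`` (lon/lat degrees), ``"metric"``
    (already planar meters), or ``"auto"`` to infer from coordinate ranges.
    """
    feats = _features(path, layer)
    if not feats:
        log.warning("%s: empty feature collection", path)
        return []

    raw: list[tuple[str, object, float]] = []
    for i, f in enumerate(feats):
        props = f.get("properties") or {}
        if damage_field not in props:
            raise KeyError(f"{path}: feature {i} lacks damage field {damage_field!r}")
        try:
            value = float(props[damage_field])
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"{path}: non-numeric damage value {props[damage_field]!r} on feature {i}"
            ) from exc
        geom = _geom_of(f)
        if geom is None or geom.is_empty:
            _reject(rejects, props.get("building_id", i), "empty geometry")
            continue
        bid = str(props.get("building_id", props.get("id", i)))
        raw.append((bid, geom, value))

    values = np.array([v for _, _, v in raw], dtype=float)
    if values.size and values.max() > 1.5:
        log.info("%s: damage values look like percentages (max %.3g); dividing by 100",
                 path, values.max())
        values = values / 100.0

    # reproject if geographic
    if raw:
        xs = [g.representative_point().x for _, g, _ in raw]
        ys = [g.representative_point().y for _, g, _ in raw]
        if _is_geographic(crs, xs, ys):
            if proj is None:
                proj = LocalProjection.from_points(xs, ys)
            raw = [(b, _project_geom(g, proj), v) for (b, g, v) in raw]

    out: list[DamagePolygon] = []
    seen: set[str] = set()
    for (bid, geom, _), frac in zip(raw, values):
        if bid in seen:
            raise ValueError(f"duplicate building_id {bid!r} in {path}")
        seen.add(bid)
        if not geom.is_valid:
            geom = make_valid(geom)
        parts = _polygon_parts(geom)
        if not parts:
            _reject(rejects, bid, "irreparable or non-polygonal geometry")
            continue
        if len(parts) == 1:
            out.append(DamagePolygon(bid, parts[0], float(frac)))
        else:
            for j, part in enumerate(parts):
                out.append(DamagePolygon(f"{bid}::{j}", part, float(frac)))
    return out


def _polygon_parts(geom) -> list:
    if geom.geom_type == "Polygon":
        return [geom] if not geom.is_empty else []
    if geom.geom_type in ("MultiPolygon", "GeometryCollection"):
        parts = []
        for g in geom.geoms:
            parts.extend(_polygon_parts(g))
        return parts
    return []


def _project_geom(geom, proj: LocalProjection):
    from shapely.ops import transform

    return transform(lambda x, y, z=None: proj.forward(np.asarray(x), np.asarray(y)), geom)


def _is_geographic(crs: str, xs, ys) -> bool:
    if crs == "geographic":
        return True
    if crs == "metric":
        return False
    if crs != "auto":
        raise ValueError(f"crs must be 'auto', 'geographic' or 'metric', got {crs!r}")
    return looks_geographic(xs, ys)


def _reject(rejects: Optional[list], rid, reason: str) -> None:
    log.warning("rejected record %r: %s", rid, reason)
    if rejects is not None:
        rejects.append({"id": rid, "reason": reason})


# ---------------------------------------------------------------------------
# damage centroids


def read_damage_centroids(
    path: str | Path,
    class_field: str = "damage_class",
    score_field: Optional[str] = None,
    score_threshold: Optional[float] = None,
    proj: Optional[LocalProjection] = None,
    crs: str = "auto",
) -> list[DamageCentroid]:
    """Read centroid-dialect model output (GeoJSON points or CSV).

    If ``score_field`` and ``score_threshold`` are both given, the binary
    class is derived as ``score >= threshold``; otherwise ``class_field``
    must hold values coercible to {0, 1}.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        rows = _read_csv(path)
        feats = []
        for r in rows:
            lon = float(r.get("lon", r.get("x")))
            lat = float(r.get("lat", r.get("y")))
            feats.append({"properties": r, "_shape": Point(lon, lat)})
    else:
        feats = _features(path)

    records: list[tuple[str, Point, int, Optional[float]]] = []
    for i, f in enumerate(feats):
        props = f.get("properties") or {}
        geom = _geom_of(f)
        if geom is None or geom.geom_type != "Point":
            raise ValueError(f"{path}: feature {i} is not a point")
        bid = str(props.get("building_id", props.get("id", i)))
        score = None
        if score_field is not None and score_threshold is not None:
            score = float(props[score_field])
            cls = int(score >= score_threshold)
        else:
            rawc = props[class_field]
            cls = int(float(rawc))
            if cls not in (0, 1) or float(rawc) not in (0.0, 1.0):
                raise ValueError(
                    f"{path}: damage class {rawc!r} outside {{0,1}} on feature {i} "
                    "(supply score_field and score_threshold for continuous scores)"
                )
        records.append((bid, geom, cls, score))

    seen: set[str] = set()
    for bid, *_ in records:
        if bid in seen:
            raise ValueError(f"duplicate building_id {bid!r} in {path}")
        seen.add(bid)

    xs = [p.x for _, p, _, _ in records]
    ys = [p.y for _, p, _, _ in records]
    if records and _is_geographic(crs, xs, ys):
        if proj is None:
            proj = LocalProjection.from_points(xs, ys)
        px, py = proj.forward(np.array(xs), np.array(ys))
        records = [
            (b, Point(float(x), float(y)), c, s)
            for (b, _, c, s), x, y in zip(records, px, py)
        ]
    return [DamageCentroid(b, p, c, s) for b, p, c, s in records]


# ---------------------------------------------------------------------------
# facilities


def _read_csv(path: Path) -> list[dict]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))


def read_facilities(
    path: str | Path,
    proj: Optional[LocalProjection] = None,
) -> list[HealthFacility]:
    """Read facility points from CSV or GeoJSON, order preserved.

    Facilities get both geographic and projected coordinates. When the file
    already carries projected ``x``/``y`` columns (as written by
    :func:`write_facilities_csv`) those are trusted, keeping the facilities
    in the same planar frame as companion building files; otherwise lon/lat
    are projected with ``proj`` (fitted to the facility centroid when not
    supplied). Unknown facility types and out-of-range lat/lon raise.
    """
    path = Path(path)
    if path.suffix.lower() in (".csv", ".tsv"):
        rows = _read_csv(path)
    else:
        rows = []
        for f in _features(path):
            props = dict(f.get("properties") or {})
            geom = _geom_of(f)
            if geom is None or geom.geom_type != "Point":
                raise ValueError(f"{path}: facility feature is not a point")
            props.setdefault("lon", geom.x)
            props.setdefault("lat", geom.y)
            rows.append(props)

    facs: list[HealthFacility] = []
    stored_xy: list[Optional[tuple[float, float]]] = []
    for i, r in enumerate(rows):
        lon, lat = float(r["lon"]), float(r["lat"])
        if not (-180.0 <= lon <= 180.0) or not (-90.0 <= lat <= 90.0):
            raise ValueError(f"{path}: row {i} lat/lon out of range ({lat}, {lon})")
        try:
            ftype = FacilityType(str(r["ftype"]).strip().lower())
        except ValueError as exc:
            raise ValueError(f"{path}: row {i} unknown facility type {r['ftype']!r}") from exc
        gold = r.get("gold_label")
        gold_val = None if gold in (None, "", "NA") else int(float(gold))
        xs_raw, ys_raw = r.get("x"), r.get("y")
        has_xy = xs_raw not in (None, "", "nan") and ys_raw not in (None, "", "nan")
        stored_xy.append((float(xs_raw), float(ys_raw)) if has_xy else None)
        facs.append(
            HealthFacility(
                facility_id=str(r.get("facility_id", i)),
                name=str(r.get("name", "")),
                ftype=ftype,
                city=str(r.get("city", "")),
                lon=lon,
                lat=lat,
                gold_label=gold_val,
            )
        )
    if facs:
        if all(xy is not None for xy in stored_xy):
            facs = [f.with_projected(*xy) for f, xy in zip(facs, stored_xy)]
        else:
            if proj is None:
                proj = LocalProjection.from_points(
                    [f.lon for f in facs], [f.lat for f in facs]
                )
            xs, ys = proj.forward(
                np.array([f.lon for f in facs]), np.array([f.lat for f in facs])
            )
            facs = [f.with_projected(float(x), float(y)) for f, x, y in zip(facs, xs, ys)]
    return facs


def read_facility_table_xlsx(
    path: str | Path,
    column_map: dict[str, str],
    sheet: Optional[str] = None,
) -> list[dict]:
    """Read a per-facility summary table from XLSX with an explicit column map.

    ``column_map`` maps canonical keys (``facility_id``, ``name``, ``ftype``,
    ``city``, ``lon``, ``lat``, ``gold_label``, ``model_a_fraction``,
    ``model_b_class``) to the spreadsheet's actual column headers. Only mapped
    columns are extracted; rows come back as dicts under the canonical keys.
    """
    import openpyxl

    wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
    ws = wb[sheet] if sheet else wb.active
    rows = ws.iter_rows(values_only=True)
    header = [str(h) if h is not None else "" for h in next(rows)]
    idx = {}
    for key, col in column_map.items():
        if col not in header:
            raise KeyError(f"{path}: mapped column {col!r} (for {key!r}) not in header {header}")
        idx[key] = header.index(col)
    out = []
    for row in rows:
        if row is None or all(v is None for v in row):
            continue
        out.append({key: row[i] for key, i in idx.items()})
    wb.close()
    return out


# ---------------------------------------------------------------------------
# deduplication


_PUNCT = re.compile(r"[^\w\s]", flags=re.UNICODE)
_WS = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Lowercase, strip punctuation, collapse whitespace."""
    return _WS.sub(" ", _PUNCT.sub(" ", name.lower())).strip()


def deduplicate_facilities(
    facilities: Sequence[HealthFacility],
    radius_m: float = 10.0,
) -> tuple[list[HealthFacility], list[dict]]:
    """Collapse duplicate facility records.

    Two records are duplicates when their normalized names match exactly and
    their projected distance is strictly below ``radius_m``. Duplicate groups
    are closed transitively; each group keeps its first-encountered record.
    Returns ``(kept, removal_log)`` where each removal entry names both the
    removed and the kept id. Idempotent.
    """
    if radius_m <= 0:
        raise ValueError("radius_m must be positive")
    n = len(facilities)
    if n == 0:
        return [], []
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    names = [normalize_name(f.name) for f in facilities]
    coords = np.array([[f.x, f.y] for f in facilities])
    if np.isnan(coords).any():
        raise ValueError("facilities must be projected before deduplication")
    tree = cKDTree(coords)
    for i, j in tree.query_pairs(r=radius_m):
        d = math.dist(coords[i], coords[j])
        if d < radius_m and names[i] == names[j]:
            union(i, j)

    kept, removed = [], []
    for i, f in enumerate(facilities):
        r = find(i)
        if r == i:
            kept.append(f)
        else:
            removed.append(
                {"removed_id": f.facility_id, "kept_id": facilities[r].facility_id}
            )
    return kept, removed


# ---------------------------------------------------------------------------
# reprojection of generic collections


def to_metric(
    features: Iterable,
    proj: LocalProjection,
) -> list:
    """Reproject a collection of records (facility / polygon / centroid) to
    planar meters with ``proj``. Warns on coordinates far from the projection
    origin, where the local projection degrades."""
    out = []
    for f in features:
        if isinstance(f, HealthFacility):
            _warn_far(f.lon, f.lat, proj)
            x, y = proj.forward(f.lon, f.lat)
            out.append(f.with_projected(x, y))
        elif isinstance(f, DamagePolygon):
            out.append(
                DamagePolygon(f.building_id, _project_geom(f.geometry, proj), f.damage_fraction)
            )
        elif isinstance(f, DamageCentroid):
            x, y = proj.forward(f.location.x, f.location.y)
            out.append(DamageCentroid(f.building_id, Point(x, y), f.damage_class, f.score))
        else:
            raise TypeError(f"cannot reproject {type(f).__name__}")
    return out


def _warn_far(lon: float, lat: float, proj: LocalProjection, limit_deg: float = 3.0) -> None:
    if abs(lon - proj.lon0) > limit_deg or abs(lat - proj.lat0) > limit_deg:
        log.warning(
            "coordinate (%.4f, %.4f) is far from projection origin (%.4f, %.4f); "
            "metric accuracy degrades",
            lon, lat, proj.lon0, proj.lat0,
        )


# ---------------------------------------------------------------------------
# writers


def write_facilities_csv(facilities: Sequence[HealthFacility], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["facility_id", "name", "ftype", "city", "lon", "lat", "x", "y", "gold_label"])
        for f in facilities:
            w.writerow(
                [
                    f.facility_id, f.name, f.ftype.value, f.city,
                    repr(f.lon), repr(f.lat), repr(f.x), repr(f.y),
                    "" if f.gold_label is None else f.gold_label,
                ]
            )


def write_calls_csv(calls: Sequence, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["facility_id", "model", "method", "damaged", "basis", "distance_m"])
        for c in calls:
            w.writerow(
                [
                    c.facility_id, c.model.value, c.method.value, int(c.damaged),
                    c.basis.value, "" if c.distance_m is None else repr(c.distance_m),
                ]
            )


def write_geojson(
    geometries: Sequence, properties: Sequence[dict], path: str | Path
) -> None:
    """Write paired geometries/property dicts as a GeoJSON FeatureCollection."""
    feats = [
        {"type": "Feature", "geometry": mapping(g), "properties": p}
        for g, p in zip(geometries, properties)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
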