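"""Individual-facility damage calls.

The individual approach overlays each facility point directly on the model
output. For the polygon dialect a facility is damaged when its point
intersects a damaged footprint, or — to rescue points that fall close to but
not inside a building — when it lies strictly within the rescue radius
(default 25 m) of a damaged footprint's centroid. For the centroid dialect
the facility takes the class of its nearest centroid within the same radius.
Both thresholds are strict inequalities.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from shapely.strtree import STRtree
from sklearn.neighbors import BallTree

from .types import (
    Basis,
    DamageCentroid,
    DamagePolygon,
    FacilityDamageCall,
    HealthFacility,
    Method,
    Model,
    Thresholds,
)

log = logging.getLogger(__name__)

__all__ = [
    "classify_polygon",
    "classify_centroid",
    "overlay_model_a",
    "overlay_model_b",
    "individual_report",
]


def classify_polygon(fraction: float, cut: float = 0.40) -> bool:
    """Damaged iff the damaged fraction strictly exceeds the cut."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"damage fraction {fraction!r} outside [0, 1]")
    return fraction > cut


def classify_centroid(damage_class: int) -> bool:
    """Damaged iff the binary class is 1."""
    if damage_class not in (0, 1):
        raise ValueError(f"damage class must be 0 or 1, got {damage_class!r}")
    return damage_class == 1


def _nearest_in_radius(
    points: np.ndarray, targets: np.ndarray, target_ids: Sequence[str], radius: float
) -> list[tuple[Optional[int], float]]:
    """For each query point: index of nearest target strictly within radius
    (ties by lowest id), plus the nearest distance (inf if no target)."""
    if len(targets) == 0:
        return [(None, float("inf"))] * len(points)
    tree = BallTree(targets)
    dist, idx = tree.query(points, k=min(len(targets), 8))
    out: list[tuple[Optional[int], float]] = []
    order = np.argsort(np.asarray(target_ids, dtype=object), kind="stable")
    rank = np.empty(len(target_ids), dtype=int)
    rank[order] = np.arange(len(target_ids))
    for drow, irow in zip(dist, idx):
        dmin = float(drow[0])
        if dmin >= radius:
            out.append((None, dmin))
            continue
        # exact distance ties broken by lowest building id
        tied = [int(i) for d, i in zip(drow, irow) if d == dmin]
        best = min(tied, key=lambda i: rank[i])
        out.append((best, dmin))
    return out


def overlay_model_a(
    facilities: Sequence[HealthFacility],
    polygons: Sequence[DamagePolygon],
    thresholds: Thresholds = Thresholds(),
) -> list[FacilityDamageCall]:
    """Intersection-plus-rescue overlay on polygon-dialect output.

    Damaged iff the facility point intersects a damaged polygon (basis
    ``intersection``; wins when both branches fire) or lies strictly within
    ``rescue_radius_m`` of a damaged polygon's centroid (basis
    ``rescue_radius``). Otherwise undamaged; the basis records whether any
    building object was nearby at all (``no_data`` when none).
    """
    calls: list[FacilityDamageCall] = []
    if not polygons:
        log.warning("empty polygon set: all facilities called undamaged / no_data")
        return [
            FacilityDamageCall(f.facility_id, Model.A, Method.individual, False, Basis.no_data)
            for f in facilities
        ]

    damaged_mask = np.array(
        [classify_polygon(p.damage_fraction, thresholds.polygon_damage_cut) for p in polygons]
    )
    geoms = [p.geometry for p in polygons]
    tree = STRtree(geoms)

    damaged_cent = np.array(
        [[g.centroid.x, g.centroid.y] for g, m in zip(geoms, damaged_mask) if m]
    ).reshape(-1, 2)
    damaged_ids = [p.building_id for p, m in zip(polygons, damaged_mask) if m]
    all_cent = np.array([[g.centroid.x, g.centroid.y] for g in geoms]).reshape(-1, 2)

    pts = np.array([[f.x, f.y] for f in facilities]).reshape(-1, 2)
    near_damaged = _nearest_in_radius(pts, damaged_cent, damaged_ids, thresholds.rescue_radius_m)
    near_any = _nearest_in_radius(
        pts, all_cent, [p.building_id for p in polygons], thresholds.rescue_radius_m
    )

    for f, (di, ddist), (ai, adist) in zip(facilities, near_damaged, near_any):
        pt = f.location
        hits = [int(i) for i in tree.query(pt, predicate="intersects")]
        hit_damaged = [i for i in hits if damaged_mask[i]]
        if hit_damaged:
            calls.append(
                FacilityDamageCall(
                    f.facility_id, Model.A, Method.individual, True, Basis.intersection, 0.0
                )
            )
        elif di is not None:
            calls.append(
                FacilityDamageCall(
                    f.facility_id, Model.A, Method.individual, True, Basis.rescue_radius, ddist
                )
            )
        elif hits:
            calls.append(
                FacilityDamageCall(
                    f.facility_id, Model.A, Method.individual, False, Basis.intersection, 0.0
                )
            )
        elif ai is not None:
            calls.append(
                FacilityDamageCall(
                    f.facility_id, Model.A, Method.individual, False, Basis.rescue_radius, adist
                )
            )
        else:
            calls.append(
                FacilityDamageCall(
                    f.facility_id, Model.A, Method.individual, False, Basis.no_data, adist
                )
            )
    return calls


def overlay_model_b(
    facilities: Sequence[HealthFacility],
    centroids: Sequence[DamageCentroid],
    thresholds: Thresholds = Thresholds(),
    match_radius_m: Optional[float] = None,
) -> list[FacilityDamageCall]:
    """Nearest-centroid-within-radius overlay on centroid-dialect output.

    The facility takes the damage class of its nearest centroid when that
    centroid lies strictly within the matching radius (defaults to the
    rescue radius); exact distance ties break to the lowest building id.
    No centroid in range -> undamaged with basis ``no_data``.
    """
    radius = thresholds.rescue_radius_m if match_radius_m is None else match_radius_m
    if not centroids:
        log.warning("empty centroid set: all facilities called undamaged / no_data")
        return [
            FacilityDamageCall(f.facility_id, Model.B, Method.individual, False, Basis.no_data)
            for f in facilities
        ]
    targets = np.array([[c.location.x, c.location.y] for c in centroids])
    ids = [c.building_id for c in centroids]
    pts = np.array([[f.x, f.y] for f in facilities]).reshape(-1, 2)
    matches = _nearest_in_radius(pts, targets, ids, radius)
    calls = []
    for f, (i, dist) in zip(facilities, matches):
        if i is None:
            calls.append(
                FacilityDamageCall(
                    f.facility_id, Model.B, Method.individual, False, Basis.no_data, dist
                )
            )
        else:
            calls.append(
                FacilityDamageCall(
                    f.facility_id,
                    Model.B,
                    Method.individual,
                    classify_centroid(centroids[i].damage_class),
                    Basis.nearest_centroid,
                    dist,
                )
            )
    return calls


def individual_report(
    calls_a: Sequence[FacilityDamageCall],
    calls_b: Sequence[FacilityDamageCall],
    facilities: Sequence[HealthFacility],
) -> pd.DataFrame:
    """Damage counts and percentages by city and facility type, per model.

    One row per (city, ftype, model) plus per-city, per-type and pooled
    rows. Percentages are recomputed from the counts and rounded to one
    decimal.
    """
    fkeys = {f.facility_id for f in facilities}
    for calls, label in ((calls_a, "A"), (calls_b, "B")):
        keys = {c.facility_id for c in calls}
        if keys != fkeys:
            missing = fkeys.symmetric_difference(keys)
            raise ValueError(f"model {label} calls do not match facility list: {sorted(missing)[:5]}")

    fac = pd.DataFrame(
        {
            "facility_id": [f.facility_id for f in facilities],
            "city": [f.city for f in facilities],
            "ftype": [f.ftype.value for f in facilities],
        }
    )
    rows = []
    for model, calls in ((Model.A, calls_a), (Model.B, calls_b)):
        dmg = pd.Series(
            {c.facility_id: c.damaged for c in calls}, name="damaged"
        )
        df = fac.join(dmg, on="facility_id")
        groups: list[tuple[str, str, pd.DataFrame]] = [
            (city, ftype, g)
            for (city, ftype), g in df.groupby(["city", "ftype"], sort=True)
        ]
        groups += [(city, "all", g) for city, g in df.groupby("city", sort=True)]
        groups += [("all", ftype, g) for ftype, g in df.groupby("ftype", sort=True)]
        groups.append(("all", "all", df))
        for city, ftype, g in groups:
            n = len(g)
            k = int(g["damaged"].sum())
            rows.append(
                {
                    "city": city,
                    "ftype": ftype,
                    "model": model.value,
                    "damaged_n": k,
                    "damaged_pct": round(100.0 * k / n, 1) if n else float("nan"),
                    "undamaged_n": n - k,
                    "undamaged_pct": round(100.0 * (n - k) / n, 1) if n else float("nan"),
                    "total": n,
                }
            )
    return pd.DataFrame(rows)
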