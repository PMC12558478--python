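"""Spatially aggregated damage calls on a fixed-area hexagonal grid.

Buildings of one model dialect are binned into flat-topped regular hexagons
of fixed area (default 0.125 km^2). Each cell's damaged proportion is
computed, non-empty cells are grouped into quartiles, and a facility is
called "likely damaged" when its cell's proportion strictly exceeds the
third quartile (configurable down to Q1/Q2).

A flat-topped hexagon of area A has edge length ``a = sqrt(2A / (3*sqrt(3)))``
(~219.3 m for 0.125 km^2). The cell centers form a triangular lattice whose
Voronoi diagram is exactly the hexagonal tiling, so assigning every point to
its nearest cell center is an exact point-in-hexagon test; boundary ties
resolve to the lowest cell id.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon

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
from .overlay import classify_centroid, classify_polygon

log = logging.getLogger(__name__)

__all__ = [
    "GridCell",
    "HexGrid",
    "hex_edge_for_area",
    "make_hex_grid",
    "aggregate_damage",
    "quartile_classify",
    "facility_cell_calls",
]

_TIE_EPS = 1e-9  # meters; distance ties below this resolve to lowest cell id


def hex_edge_for_area(area_m2: float) -> float:
    """Edge length of a regular hexagon with the given area."""
    return math.sqrt(2.0 * area_m2 / (3.0 * math.sqrt(3.0)))


@dataclass
class GridCell:
    cell_id: int
    center: tuple[float, float]
    edge: float
    building_count: int = 0
    damaged_count: int = 0
    quartile: str = "empty"  # Q1..Q4 or "empty"

    @property
    def proportion(self) -> float:
        """Damaged proportion; NaN when the cell holds no buildings."""
        if self.building_count == 0:
            return float("nan")
        return self.damaged_count / self.building_count

    @property
    def polygon(self) -> Polygon:
        cx, cy = self.center
        a = self.edge
        pts = [
            (cx + a * math.cos(math.radians(60 * k)), cy + a * math.sin(math.radians(60 * k)))
            for k in range(6)
        ]
        return Polygon(pts)


@dataclass
class HexGrid:
    cells: list[GridCell]
    edge: float
    anchor: tuple[float, float]
    _tree: Optional[cKDTree] = field(default=None, repr=False, compare=False)

    def _kdtree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(np.array([c.center for c in self.cells]))
        return self._tree

    def assign(self, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        """Cell index for each point: nearest cell center (exact for the
        hexagonal Voronoi tiling), ties to the lowest cell id."""
        pts = np.column_stack([np.asarray(xs, float), np.asarray(ys, float)])
        tree = self._kdtree()
        k = min(len(self.cells), 3)
        dist, idx = tree.query(pts, k=k)
        if k == 1:
            return np.asarray(idx, int).reshape(-1)
        out = np.empty(len(pts), dtype=int)
        for i, (drow, irow) in enumerate(zip(dist, idx)):
            tied = irow[drow <= drow[0] + _TIE_EPS]
            out[i] = int(tied.min())
        return out


def make_hex_grid(
    bounds: tuple[float, float, float, float],
    cell_area_km2: float = 0.125,
) -> HexGrid:
    """Tile a bounding rectangle with flat-topped hexagons of fixed area.

    The grid is anchored at the lower-left corner of the bounds (a cell
    center sits there) and extends one lattice pitch beyond every side so
    that each point of the bounds has its nearest center in the grid.
    """
    x0, y0, x1, y1 = bounds
    if x1 <= x0 or y1 <= y0:
        raise ValueError("bounds must be a non-degenerate rectangle")
    if cell_area_km2 <= 0:
        raise ValueError("cell_area_km2 must be positive")
    a = hex_edge_for_area(cell_area_km2 * 1e6)
    dx = 1.5 * a            # column pitch
    dy = math.sqrt(3.0) * a  # row pitch

    ncol = int(math.ceil((x1 - x0) / dx)) + 2
    nrow = int(math.ceil((y1 - y0) / dy)) + 2
    cells: list[GridCell] = []
    cid = 0
    for row in range(-1, nrow + 1):
        for col in range(-1, ncol + 1):
            cx = x0 + col * dx
            cy = y0 + row * dy + (dy / 2 if col % 2 else 0.0)
            cells.append(GridCell(cell_id=cid, center=(cx, cy), edge=a))
            cid += 1
    return HexGrid(cells=cells, edge=a, anchor=(x0, y0))


def _representative_points(objects: Sequence) -> np.ndarray:
    pts = []
    for o in objects:
        if isinstance(o, DamagePolygon):
            c = o.geometry.centroid
            pts.append((c.x, c.y))
        elif isinstance(o, DamageCentroid):
            pts.append((o.location.x, o.location.y))
        else:
            raise TypeError(f"cannot aggregate {type(o).__name__}")
    return np.array(pts).reshape(-1, 2)


def aggregate_damage(
    objects: Sequence,
    grid: HexGrid,
    thresholds: Thresholds = Thresholds(),
) -> HexGrid:
    """Count buildings and damaged buildings of one model dialect per cell.

    Polygon-dialect objects are represented by their footprint centroid;
    centroid-dialect objects by the point itself. Each building lands in
    exactly one cell; counts are written onto the grid in place (and the
    grid returned). Buildings are damaged under the standard binary rules.
    """
    for c in grid.cells:
        c.building_count = 0
        c.damaged_count = 0
    if not objects:
        return grid
    pts = _representative_points(objects)
    damaged = np.array(
        [
            classify_polygon(o.damage_fraction, thresholds.polygon_damage_cut)
            if isinstance(o, DamagePolygon)
            else classify_centroid(o.damage_class)
            for o in objects
        ]
    )
    idx = grid.assign(pts[:, 0], pts[:, 1])
    for i, d in zip(idx, damaged):
        grid.cells[i].building_count += 1
        if d:
            grid.cells[i].damaged_count += 1
    return grid


def quartile_classify(
    grid: HexGrid,
    quartile_cut: str = "Q3",
    interpolation: str = "linear",
) -> tuple[HexGrid, float]:
    """Label non-empty cells Q1–Q4 by damaged proportion; return the cut value.

    Quartile breaks use the requested estimator (numpy percentile method)
    over *non-empty* cells only; empty cells stay labelled ``empty``.
    Returns ``(grid, cut_value)`` where the cut value is the quartile named
    by ``quartile_cut`` (default the third quartile).
    """
    props = np.array([c.proportion for c in grid.cells if c.building_count > 0])
    if props.size < 4:
        raise ValueError(f"need at least 4 non-empty cells for quartiles, have {props.size}")
    q1, q2, q3 = np.percentile(props, [25, 50, 75], method=interpolation)
    for c in grid.cells:
        if c.building_count == 0:
            c.quartile = "empty"
            continue
        p = c.proportion
        if p <= q1:
            c.quartile = "Q1"
        elif p <= q2:
            c.quartile = "Q2"
        elif p <= q3:
            c.quartile = "Q3"
        else:
            c.quartile = "Q4"
    cut_value = {"Q1": q1, "Q2": q2, "Q3": q3}[quartile_cut]
    return grid, float(cut_value)


def facility_cell_calls(
    facilities: Sequence[HealthFacility],
    grid: HexGrid,
    cut_value: float,
    model: Model,
) -> list[FacilityDamageCall]:
    """Aggregated-method calls: damaged iff the facility's cell proportion
    strictly exceeds the quartile cut; empty cell -> undamaged / no_data."""
    if not facilities:
        return []
    idx = grid.assign(
        np.array([f.x for f in facilities]), np.array([f.y for f in facilities])
    )
    calls = []
    for f, i in zip(facilities, idx):
        cell = grid.cells[i]
        if cell.building_count == 0:
            calls.append(
                FacilityDamageCall(f.facility_id, model, Method.aggregated, False, Basis.no_data)
            )
        else:
            calls.append(
                FacilityDamageCall(
                    f.facility_id,
                    model,
                    Method.aggregated,
                    bool(cell.proportion > cut_value),
                    Basis.cell_quartile,
                )
            )
    return calls
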