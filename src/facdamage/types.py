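"""Domain record types shared across the pipeline.

Two building-damage dialects are handled throughout:

* the *polygon* dialect — building footprint polygons carrying a continuous
  damaged fraction (the share of footprint pixels a segmentation model labels
  damaged), and
* the *centroid* dialect — building centroid points carrying a binary damage
  class (1 = major damage/destroyed, 0 = none/minor).

Facilities are typed points (hospital, dialysis center, pharmacy) tagged with
a city label and, when available, a gold-standard damage label.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

from shapely.geometry import Point, Polygon

__all__ = [
    "FacilityType",
    "DamagePolygon",
    "DamageCentroid",
    "HealthFacility",
    "Thresholds",
    "FacilityDamageCall",
    "Model",
    "Method",
    "Basis",
]


class FacilityType(str, Enum):
    hospital = "hospital"
    dialysis = "dialysis"
    pharmacy = "pharmacy"


class Model(str, Enum):
    A = "A"  # polygon dialect
    B = "B"  # centroid dialect


class Method(str, Enum):
    individual = "individual"
    aggregated = "aggregated"


class Basis(str, Enum):
    intersection = "intersection"
    rescue_radius = "rescue_radius"
    nearest_centroid = "nearest_centroid"
    cell_quartile = "cell_quartile"
    no_data = "no_data"


@dataclass
class DamagePolygon:
    building_id: str
    geometry: Polygon  # planar meters
    damage_fraction: float  # in [0, 1]

    def __post_init__(self) -> None:
        if not (0.0 <= self.damage_fraction <= 1.0):
            raise ValueError(
                f"damage_fraction {self.damage_fraction!r} outside [0, 1] "
                f"for building {self.building_id!r}"
            )


@dataclass
class DamageCentroid:
    building_id: str
    location: Point  # planar meters
    damage_class: int  # 0 or 1
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.damage_class not in (0, 1):
            raise ValueError(
                f"damage_class must be 0 or 1, got {self.damage_class!r} "
                f"for building {self.building_id!r}"
            )


@dataclass
class HealthFacility:
    facility_id: str
    name: str
    ftype: FacilityType
    city: str
    lon: float
    lat: float
    x: float = float("nan")  # projected meters
    y: float = float("nan")
    gold_label: Optional[int] = None

    @property
    def location(self) -> Point:
        return Point(self.x, self.y)

    def with_projected(self, x: float, y: float) -> "HealthFacility":
        return replace(self, x=x, y=y)


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds for both damage-report methods.

    ``polygon_damage_cut``: a polygon-dialect building is damaged when its
    damaged fraction *strictly exceeds* this cut (default 0.40).
    ``rescue_radius_m``: a facility within (strictly) this distance of a
    damaged building centroid is marked damaged even without a footprint
    intersection (default 25 m).
    ``cell_area_km2``: hexagonal cell area for the aggregated method.
    ``quartile_cut``: facilities in cells whose damaged proportion strictly
    exceeds this quartile of non-empty cells are called damaged.
    ``alpha``: two-sided level for all confidence intervals.
    """

    polygon_damage_cut: float = 0.40
    rescue_radius_m: float = 25.0
    cell_area_km2: float = 0.125
    quartile_cut: str = "Q3"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.polygon_damage_cut < 1.0):
            raise ValueError("polygon_damage_cut must be in (0, 1)")
        if self.rescue_radius_m <= 0 or self.cell_area_km2 <= 0:
            raise ValueError("rescue_radius_m and cell_area_km2 must be positive")
        if self.quartile_cut not in ("Q1", "Q2", "Q3"):
            raise ValueError("quartile_cut must be one of Q1, Q2, Q3")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class FacilityDamageCall:
    """One binary damaged/undamaged decision: facility x model x method."""

    facility_id: str
    model: Model
    method: Method
    damaged: bool
    basis: Basis
    distance_m: Optional[float] = None
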