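"""Individual overlay: classification rules, rescue radius, report table."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from shapely.geometry import Point, Polygon, box

from facdamage.overlay import (
    classify_centroid,
    classify_polygon,
    individual_report,
    overlay_model_a,
    overlay_model_b,
)
from facdamage.synthetic import CityParams, ErrorParams, generate_city
from facdamage.types import (
    Basis,
    DamageCentroid,
    DamagePolygon,
    FacilityType,
    HealthFacility,
    Thresholds,
)
from oracles import brute_overlay_a, brute_overlay_b


def fac(fid, x, y, ftype=FacilityType.pharmacy, city="c"):
    return HealthFacility(facility_id=fid, name=fid, ftype=ftype, city=city,
                          lon=36.0, lat=36.0, x=x, y=y)


def poly(bid, x, y, frac, s=10.0):
    return DamagePolygon(bid, box(x, y, x + s, y + s), frac)


# ---------------------------------------------------------------------------
# binary rules


def test_polygon_rule_is_strict_greater_than():
    assert classify_polygon(0.50, 0.40)
    assert not classify_polygon(0.40, 0.40)  # boundary: strictly greater
    assert not classify_polygon(0.0, 0.40)
    with pytest.raises(ValueError):
        classify_polygon(1.2, 0.40)


def test_centroid_rule():
    assert classify_centroid(1)
    assert not classify_centroid(0)
    with pytest.raises(ValueError):
        classify_centroid(2)


# ---------------------------------------------------------------------------
# polygon-dialect overlay


def test_point_in_damaged_polygon_is_intersection_basis():
    calls = overlay_model_a([fac("f", 5, 5)], [poly("b", 0, 0, 0.6)])
    assert calls[0].damaged and calls[0].basis is Basis.intersection


def test_point_in_undamaged_polygon_rescued_by_nearby_damaged_centroid():
    # facility inside an undamaged footprint, 20 m from a damaged centroid
    facs = [fac("f", 5, 5)]
    polys = [poly("u", 0, 0, 0.1), poly("d", 20, 0, 0.9)]  # centroid (25, 5)
    calls = overlay_model_a(facs, polys)
    assert calls[0].damaged and calls[0].basis is Basis.rescue_radius
    assert calls[0].distance_m == pytest.approx(20.0)


def test_point_beyond_radius_of_everything_is_undamaged():
    facs = [fac("f", 500, 500)]
    polys = [poly("d", 0, 0, 0.9)]
    calls = overlay_model_a(facs, polys)
    assert not calls[0].damaged and calls[0].basis is Basis.no_data


def test_rescue_radius_is_strict():
    # damaged centroid exactly 25 m away: not rescued
    polys = [poly("d", 0, 0, 0.9)]  # centroid (5, 5)
    calls = overlay_model_a([fac("f", 30.0, 5.0)], polys)
    assert not calls[0].damaged
    calls = overlay_model_a([fac("f", 29.999, 5.0)], polys)
    assert calls[0].damaged and calls[0].basis is Basis.rescue_radius


def test_empty_polygon_set_yields_no_data_calls():
    calls = overlay_model_a([fac("f", 0, 0)], [])
    assert calls == [
        type(calls[0])("f", calls[0].model, calls[0].method, False, Basis.no_data)
    ] or (not calls[0].damaged and calls[0].basis is Basis.no_data)


# ---------------------------------------------------------------------------
# centroid-dialect overlay


def cent(bid, x, y, cls):
    return DamageCentroid(bid, Point(x, y), cls)


def test_nearest_centroid_class_is_taken():
    calls = overlay_model_b([fac("f", 0, 0)], [cent("c", 5, 0, 1)])
    assert calls[0].damaged and calls[0].basis is Basis.nearest_centroid
    assert calls[0].distance_m == pytest.approx(5.0)


def test_nearest_undamaged_wins_over_second_nearest_damaged():
    calls = overlay_model_b(
        [fac("f", 0, 0)], [cent("near", 5, 0, 0), cent("far", 8, 0, 1)]
    )
    assert not calls[0].damaged and calls[0].basis is Basis.nearest_centroid


def test_no_centroid_within_radius_is_no_data():
    calls = overlay_model_b([fac("f", 0, 0)], [cent("c", 40, 0, 1)])
    assert not calls[0].damaged and calls[0].basis is Basis.no_data


def test_exact_distance_tie_breaks_to_lowest_building_id():
    tied = [cent("z", 10, 0, 0), cent("a", -10, 0, 1)]
    calls = overlay_model_b([fac("f", 0, 0)], tied)
    assert calls[0].damaged  # "a" (class 1) sorts before "z"


# ---------------------------------------------------------------------------
# invariants


@pytest.fixture(scope="module")
def city():
    return generate_city(
        CityParams(n_buildings=150, bounds=(0, 0, 1200, 1200), decay_scale_m=350,
                   n_hospitals=4, n_dialysis=2, n_pharmacies=40),
        ErrorParams(), seed=5,
    )


def test_raising_damage_cut_never_increases_damaged_count(city):
    counts = []
    for cut in (0.2, 0.3, 0.4, 0.5, 0.7, 0.9):
        th = Thresholds(polygon_damage_cut=cut)
        calls = overlay_model_a(city.facilities, city.model_a, th)
        counts.append(sum(c.damaged for c in calls))
    assert counts == sorted(counts, reverse=True)


def test_shrinking_rescue_radius_never_increases_damaged_count(city):
    counts = []
    for radius in (50, 25, 10, 5, 1):
        th = Thresholds(rescue_radius_m=radius)
        calls = overlay_model_a(city.facilities, city.model_a, th)
        counts.append(sum(c.damaged for c in calls))
    assert counts == sorted(counts, reverse=True)


def test_zero_damage_input_yields_zero_damaged_facilities(city):
    polys = [DamagePolygon(p.building_id, p.geometry, 0.0) for p in city.model_a]
    cents = [DamageCentroid(c.building_id, c.location, 0) for c in city.model_b]
    assert not any(c.damaged for c in overlay_model_a(city.facilities, polys))
    assert not any(c.damaged for c in overlay_model_b(city.facilities, cents))


def test_overlay_is_invariant_to_record_order(city):
    rng = np.random.default_rng(0)
    base_a = {c.facility_id: (c.damaged, c.basis) for c in
              overlay_model_a(city.facilities, city.model_a)}
    base_b = {c.facility_id: (c.damaged, c.basis) for c in
              overlay_model_b(city.facilities, city.model_b)}
    facs = list(city.facilities)
    polys = list(city.model_a)
    cents = list(city.model_b)
    for _ in range(3):
        rng.shuffle(facs), rng.shuffle(polys), rng.shuffle(cents)
        got_a = {c.facility_id: (c.damaged, c.basis) for c in
                 overlay_model_a(facs, polys)}
        got_b = {c.facility_id: (c.damaged, c.basis) for c in
                 overlay_model_b(facs, cents)}
        assert got_a == base_a
        assert got_b == base_b


@pytest.mark.parametrize("seed", range(5))
def test_overlay_matches_bruteforce_on_random_cities(seed):
    city = generate_city(
        CityParams(n_buildings=120, bounds=(0, 0, 1100, 1100), decay_scale_m=350,
                   n_hospitals=3, n_dialysis=2, n_pharmacies=30),
        ErrorParams(), seed=seed,
    )
    th = Thresholds()
    got_a = {c.facility_id: c.damaged for c in
             overlay_model_a(city.facilities, city.model_a, th)}
    assert got_a == brute_overlay_a(city.facilities, city.model_a,
                                    th.polygon_damage_cut, th.rescue_radius_m)
    got_b = {c.facility_id: c.damaged for c in
             overlay_model_b(city.facilities, city.model_b, th)}
    assert got_b == brute_overlay_b(city.facilities, city.model_b, th.rescue_radius_m)


# ---------------------------------------------------------------------------
# report table


def _mass_calls(n_damaged, n_total, ftype=FacilityType.pharmacy, city="c"):
    facs = [fac(f"f{i}", i * 100.0, 0.0, ftype, city) for i in range(n_total)]
    polys = [poly(f"b{i}", i * 100.0 - 5, -5, 0.9 if i < n_damaged else 0.0)
             for i in range(n_total)]
    calls = overlay_model_a(facs, polys)
    return facs, calls


def test_pooled_percentages_round_to_one_decimal():
    facs, calls_a = _mass_calls(51, 492)
    calls_b = overlay_model_b(
        facs, [cent(f"c{i}", i * 100.0, 0.0, 1 if i < 21 else 0) for i in range(492)]
    )
    table = individual_report(calls_a, calls_b, facs)
    pooled = table[(table.city == "all") & (table.ftype == "all")]
    row_a = pooled[pooled.model == "A"].iloc[0]
    row_b = pooled[pooled.model == "B"].iloc[0]
    assert (row_a.damaged_n, row_a.damaged_pct) == (51, 10.4)
    assert (row_b.damaged_n, row_b.damaged_pct) == (21, 4.3)
    assert row_a.undamaged_n == 441 and row_a.undamaged_pct == 89.6


def test_type_stratum_percentage():
    facs, calls_a = _mass_calls(46, 454)
    calls_b = overlay_model_b(
        facs, [cent(f"c{i}", i * 100.0, 0.0, 0) for i in range(454)]
    )
    table = individual_report(calls_a, calls_b, facs)
    row = table[(table.ftype == "pharmacy") & (table.model == "A")
                & (table.city == "all")].iloc[0]
    assert (row.damaged_n, row.damaged_pct) == (46, 10.1)
    zero = table[(table.model == "B") & (table.city == "all") & (table.ftype == "all")].iloc[0]
    assert (zero.damaged_n, zero.damaged_pct) == (0, 0.0)


def test_report_requires_matching_call_sets():
    facs, calls_a = _mass_calls(1, 5)
    calls_b = overlay_model_b(facs[:-1], [cent("c", 0, 0, 1)])
    with pytest.raises(ValueError, match="match"):
        individual_report(calls_a, calls_b, facs)
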