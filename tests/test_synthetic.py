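"""Synthetic city generator: layout, damage field, model error modes."""

import hashlib
import math
from pathlib import Path

import numpy as np
import pytest
from shapely.geometry import box

from facdamage.synthetic import (
    CityParams,
    ErrorParams,
    SyntheticBuilding,
    assign_true_damage,
    generate_buildings,
    generate_city,
    place_facilities,
    simulate_model_a,
    simulate_model_b,
    wing_fractions,
    write_city,
)
from facdamage.types import FacilityType

BOUNDS = (0.0, 0.0, 1500.0, 1500.0)


# ---------------------------------------------------------------------------
# building layout


def test_building_layout_deterministic():
    a = generate_buildings(10, BOUNDS, 0.5, seed=1)
    b = generate_buildings(10, BOUNDS, 0.5, seed=1)
    assert [x.footprint.wkt for x in a] == [y.footprint.wkt for y in b]


def test_sparse_only_layout_respects_spacing():
    bl = generate_buildings(100, (0, 0, 3000, 3000), 0.0, seed=2, sparse_spacing_m=15.0)
    assert all(b.zone == "sparse" for b in bl)
    for i in range(len(bl)):
        for j in range(i + 1, len(bl)):
            assert bl[i].footprint.distance(bl[j].footprint) >= 15.0 - 1e-9


def test_footprints_never_overlap_bruteforce():
    bl = generate_buildings(50, BOUNDS, 0.6, seed=3)
    for i in range(len(bl)):
        for j in range(i + 1, len(bl)):
            inter = bl[i].footprint.intersection(bl[j].footprint)
            assert inter.is_empty or inter.area == 0.0


def test_dense_cluster_gaps_below_merge_distance():
    bl = generate_buildings(60, BOUNDS, 1.0, seed=4, merge_gap_max_m=5.0)
    clusters: dict[int, list[SyntheticBuilding]] = {}
    for b in bl:
        clusters.setdefault(b.cluster, []).append(b)
    for members in clusters.values():
        if len(members) < 2:
            continue
        for b in members:
            gap = min(
                b.footprint.distance(o.footprint) for o in members if o is not b
            )
            assert gap < 5.0


def test_impossible_bounds_raise():
    with pytest.raises(RuntimeError, match="tries"):
        generate_buildings(500, (0, 0, 100, 100), 0.0, seed=5, max_tries=500)


# ---------------------------------------------------------------------------
# damage field


def _mkbuilding(x, y, w=10.0, h=10.0, size="small", zone="sparse", i=0):
    return SyntheticBuilding(
        building_id=f"t{i}", footprint=box(x, y, x + w, y + h),
        zone=zone, size_class=size, cluster=-1, slot=(0, 0),
    )


def test_damage_field_closed_forms():
    b0 = _mkbuilding(-5, -5)  # centroid exactly at the epicenter
    d0 = 400.0
    b1 = _mkbuilding(d0 * math.log(2) - 5, -5)  # centroid at distance d0*ln 2
    assign_true_damage([b0, b1], (0.0, 0.0), d0, noise_sd=0.0,
                       destruction_cut=0.8, seed=0)
    assert b0.true_damage_fraction == pytest.approx(1.0)
    assert b0.destroyed
    assert b1.true_damage_fraction == pytest.approx(0.5)
    assert not b1.destroyed


def test_noisy_damage_mean_matches_noise_free_mean():
    n = 1000
    rng = np.random.default_rng(0)
    bl = [_mkbuilding(x, y, i=i) for i, (x, y) in
          enumerate(rng.uniform(150, 900, size=(n, 2)))]
    assign_true_damage(bl, (0, 0), 500.0, noise_sd=0.0, destruction_cut=0.8, seed=1)
    clean_mean = np.mean([b.true_damage_fraction for b in bl])
    assign_true_damage(bl, (0, 0), 500.0, noise_sd=0.1, destruction_cut=0.8, seed=1)
    noisy = np.array([b.true_damage_fraction for b in bl])
    # clamping is rare in this range, so the noise-free mean is the target
    se = noisy.std(ddof=1) / math.sqrt(n)
    assert abs(noisy.mean() - clean_mean) < 3 * se + 0.01


# ---------------------------------------------------------------------------
# model A simulation


def _damage_pair(frac_a, frac_b, wa=100.0, wb=300.0):
    """Two adjacent dense-cluster buildings with set areas and fractions."""
    a = SyntheticBuilding("a", box(0, 0, 10, wa / 10), "dense", "small", 0, (0, 0),
                          true_damage_fraction=frac_a)
    b = SyntheticBuilding("b", box(12, 0, 22, wb / 10), "dense", "small", 0, (0, 1),
                          true_damage_fraction=frac_b)
    return [a, b]


def test_model_a_identity_when_error_free(clean_city):
    truth = {b.building_id: b.true_damage_fraction for b in clean_city.buildings}
    assert len(clean_city.model_a) == len(clean_city.buildings)
    for p in clean_city.model_a:
        assert p.damage_fraction == truth[p.building_id]


def test_merged_pair_fraction_is_area_weighted_mean():
    pair = _damage_pair(1.0, 0.0)
    out = simulate_model_a(pair, ErrorParams(p_merge=1.0, p_destroyed_miss=0.0), seed=0)
    assert len(out) == 1
    merged = out[0]
    assert merged.building_id == "a+b"
    assert merged.damage_fraction == pytest.approx(0.25)  # (1*100 + 0*300) / 400
    assert merged.geometry.contains(pair[0].footprint)
    assert merged.geometry.contains(pair[1].footprint)


def test_destroyed_miss_suppresses_every_destroyed_building():
    rng = np.random.default_rng(7)
    bl = [_mkbuilding(x, y, i=i) for i, (x, y) in
          enumerate(rng.uniform(0, 800, size=(200, 2)))]
    assign_true_damage(bl, (400, 400), 500.0, 0.15, destruction_cut=0.8, seed=2)
    destroyed = {b.building_id for b in bl if b.destroyed}
    assert destroyed  # precondition for a meaningful check
    out = simulate_model_a(bl, ErrorParams(p_merge=0, p_destroyed_miss=1.0), seed=3)
    for p in out:
        if p.building_id in destroyed:
            assert p.damage_fraction <= 0.2  # classified undamaged at the 0.40 cut


# ---------------------------------------------------------------------------
# model B simulation


def test_model_b_identity_when_error_free(clean_city):
    truth = {b.building_id: b.true_damage_fraction for b in clean_city.buildings}
    assert len(clean_city.model_b) == len(clean_city.buildings)
    for c in clean_city.model_b:
        assert c.damage_class == int(truth[c.building_id] > 0.40)


def test_wing_partition_concentrates_damage():
    assert wing_fractions(1 / 3, 3, from_left=True) == pytest.approx([1.0, 0.0, 0.0])
    assert wing_fractions(1 / 3, 3, from_left=False) == pytest.approx([0.0, 0.0, 1.0])
    for f in (0.0, 0.2, 0.5, 0.9, 1.0):
        for k in (2, 3):
            wf = wing_fractions(f, k)
            assert np.mean(wf) == pytest.approx(f)
            assert all(0.0 <= w <= 1.0 for w in wf)


def test_one_damaged_wing_flags_whole_building():
    b = _mkbuilding(0, 0, w=60, h=30, size="large")
    b.true_damage_fraction = 1 / 3  # below the 0.40 building-level cut
    out = simulate_model_b([b], ErrorParams(p_multi_centroid=1.0, p_destroyed_miss=0.0),
                           seed=1)
    assert len(out) in (2, 3)
    assert sum(c.damage_class for c in out) == 1  # exactly one damaged wing
    for c in out:
        assert b.footprint.contains(c.location)


def test_multi_centroid_count_matches_binomial_expectation():
    rng = np.random.default_rng(11)
    n_large = 30
    extra_counts = []
    p = 0.5
    for seed in range(200):
        bl = [_mkbuilding(i * 100.0, 0, w=40, h=40, size="large", i=i)
              for i in range(n_large)]
        assign_true_damage(bl, (0, 0), 500.0, 0.1, 0.8, seed=seed)
        out = simulate_model_b(bl, ErrorParams(p_multi_centroid=p, p_destroyed_miss=0),
                               seed=seed)
        extra_counts.append(len(out) - n_large)
    # each affected building adds k-1 in {1,2} extra centroids, k uniform:
    # E[extra] = n * p * 1.5, Var per building = p*(1*1 + ...):
    mean = np.mean(extra_counts)
    expected = n_large * p * 1.5
    se = np.std(extra_counts, ddof=1) / math.sqrt(len(extra_counts))
    assert abs(mean - expected) < 3 * se


# ---------------------------------------------------------------------------
# facilities


def _hosting_city(seed=5):
    bl = generate_buildings(80, BOUNDS, 0.4, seed=seed)
    assign_true_damage(bl, (750, 750), 400.0, 0.1, 0.8, seed=seed)
    return bl


def test_exact_geocoding_places_points_inside_hosts():
    bl = _hosting_city()
    facs = place_facilities(
        bl, {FacilityType.hospital: 2, FacilityType.dialysis: 1, FacilityType.pharmacy: 10},
        ErrorParams.none(), seed=1,
    )
    assert len(facs) == 13
    tally = {t: sum(1 for f in facs if f.ftype is t) for t in FacilityType}
    assert tally == {FacilityType.hospital: 2, FacilityType.dialysis: 1,
                     FacilityType.pharmacy: 10}
    by_id = {b.building_id: b for b in bl}
    hosts = [min(bl, key=lambda b: b.footprint.distance(f.location)) for f in facs]
    for f, h in zip(facs, hosts):
        assert h.footprint.contains(f.location)
        assert f.gold_label == int(h.true_damage_fraction > 0.40)


def test_hospitals_only_on_large_buildings():
    bl = _hosting_city()
    facs = place_facilities(bl, {FacilityType.hospital: 3}, ErrorParams.none(), seed=2)
    for f in facs:
        host = min(bl, key=lambda b: b.footprint.distance(f.location))
        assert host.size_class == "large"


def test_geocode_outside_displaces_points_just_off_the_footprint():
    bl = _hosting_city()
    facs = place_facilities(
        bl, {FacilityType.pharmacy: 15},
        ErrorParams(p_geocode_outside=1.0, geocode_sigma_m=0.0,
                    p_merge=0, p_multi_centroid=0, p_destroyed_miss=0),
        seed=3,
    )
    for f in facs:
        d = min(b.footprint.distance(f.location) for b in bl)
        host = min(bl, key=lambda b: b.footprint.distance(f.location))
        assert not host.footprint.contains(f.location)
        assert 0.0 < host.footprint.exterior.distance(f.location) <= 5.0 + 1e-9


def test_facility_count_exceeding_hosts_raises():
    bl = _hosting_city()
    n_large = sum(1 for b in bl if b.size_class == "large")
    with pytest.raises(ValueError, match="exceeds"):
        place_facilities(bl, {FacilityType.hospital: n_large + 1},
                         ErrorParams.none(), seed=4)


# ---------------------------------------------------------------------------
# whole-city determinism


def _dir_digest(d: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(d.iterdir()):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()


def test_city_serialization_is_byte_identical_across_runs(tmp_path):
    params = CityParams(n_buildings=60, bounds=(0, 0, 900, 900),
                        n_hospitals=2, n_dialysis=1, n_pharmacies=8)
    for run in ("one", "two"):
        write_city(generate_city(params, ErrorParams(), seed=42), tmp_path / run)
    assert _dir_digest(tmp_path / "one") == _dir_digest(tmp_path / "two")


def test_provenance_regenerates_city(tmp_path):
    params = CityParams(n_buildings=60, bounds=(0, 0, 900, 900),
                        n_hospitals=2, n_dialysis=1, n_pharmacies=8)
    city = generate_city(params, ErrorParams(p_merge=0.4), seed=9)
    prov = city.provenance
    params2 = CityParams(**{
        k: tuple(v) if isinstance(v, list) else v for k, v in prov["city"].items()
    })
    city2 = generate_city(params2, ErrorParams(**prov["errors"]), prov["seed"])
    assert [b.footprint.wkt for b in city.buildings] == [
        b.footprint.wkt for b in city2.buildings
    ]
    assert [f.x for f in city.facilities] == [f.x for f in city2.facilities]
    assert [p.damage_fraction for p in city.model_a] == [
        p.damage_fraction for p in city2.model_a
    ]
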