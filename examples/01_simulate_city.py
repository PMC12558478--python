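"""Generate a synthetic post-earthquake city and write it to disk.

The city bundles everything downstream stages need: building footprints
with a known true-damage field, two model-output dialects with injected
error modes, and facilities with gold-standard labels.
"""

from facdamage import CityParams, ErrorParams, generate_city, write_city

params = CityParams(n_buildings=150, bounds=(0, 0, 1200, 1200),
                    n_hospitals=4, n_dialysis=2, n_pharmacies=40)
city = generate_city(params, ErrorParams(), seed=11)
write_city(city, "scratch_city")

n_damaged = sum(b.true_damage_fraction > 0.40 for b in city.buildings)
n_destroyed = sum(b.destroyed for b in city.buildings)
print(f"buildings: {len(city.buildings)} "
      f"({n_damaged} truly damaged >40%, {n_destroyed} destroyed)")
print(f"facilities: {len(city.facilities)} "
      f"({sum(f.gold_label for f in city.facilities)} on damaged buildings)")
print(f"model outputs: {len(city.model_a)} polygons, {len(city.model_b)} centroids")
# Polygon count < building count when merging fused adjacent pairs;
# centroid count > building count when large buildings got one per wing.
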