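"""Monte-Carlo benchmark: how destroyed-building misses erode sensitivity.

Sweeps the probability that a completely destroyed building is emitted as
undamaged, regenerating cities across seeds and measuring the recovered
facility-level sensitivity for both model dialects.
"""

from facdamage import CityParams, ErrorParams, run_synthetic_benchmark
from facdamage.pipeline import summarize_benchmark

grid = [ErrorParams(p_merge=0, p_multi_centroid=0, geocode_sigma_m=0,
                    p_geocode_outside=0, p_destroyed_miss=p)
        for p in (0.0, 0.5, 1.0)]
bench = run_synthetic_benchmark(
    grid, n_seeds=20,
    city_params=CityParams(n_buildings=150, bounds=(0, 0, 1200, 1200),
                           decay_scale_m=350,
                           n_hospitals=4, n_dialysis=2, n_pharmacies=40),
    method="individual", base_seed=7,
)
summary = summarize_benchmark(bench)
for i, p in enumerate((0.0, 0.5, 1.0)):
    row = summary.loc[i]
    print(f"p(destroyed miss) = {p:.1f}: "
          f"sensitivity A = {row.sens_a_individual:.3f} "
          f"(+/- {row.sens_a_individual_se:.3f}), "
          f"B = {row.sens_b_individual:.3f} "
          f"(+/- {row.sens_b_individual_se:.3f})")
# Sensitivity falls monotonically as more rubble goes unrecognized — the
# single error mode with the most direct cost for facility-level reports.
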