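"""Agreement and accuracy: Cohen's kappa and exact binomial intervals.

Compares the two dialects' calls against each other (kappa) and against the
gold-standard labels (sensitivity/specificity with Clopper-Pearson 95% CIs).
"""

from facdamage import (
    CityParams, ErrorParams, Thresholds, cohens_kappa, confusion,
    generate_city, overlay_model_a, overlay_model_b, sens_spec,
)

city = generate_city(CityParams(n_buildings=150, bounds=(0, 0, 1200, 1200),
                                n_hospitals=4, n_dialysis=2, n_pharmacies=40),
                     ErrorParams(), seed=11)
calls_a = {c.facility_id: int(c.damaged)
           for c in overlay_model_a(city.facilities, city.model_a)}
calls_b = {c.facility_id: int(c.damaged)
           for c in overlay_model_b(city.facilities, city.model_b)}
gold = {f.facility_id: f.gold_label for f in city.facilities}

agr = cohens_kappa(list(calls_a.values()),
                   [calls_b[k] for k in calls_a])
print(f"model agreement: kappa = {agr.kappa:.2f} "
      f"(95% CI {agr.ci_low:.2f} to {agr.ci_high:.2f}, n = {agr.n})")

for label, calls in (("A", calls_a), ("B", calls_b)):
    table, _ = confusion(calls, gold)
    acc = sens_spec(table, alpha=0.05)
    print(f"model {label}: sensitivity {100 * acc.sensitivity:.2f}% "
          f"(95% CI {100 * acc.sens_ci[0]:.2f} to {100 * acc.sens_ci[1]:.2f}), "
          f"specificity {100 * acc.specificity:.2f}% "
          f"(95% CI {100 * acc.spec_ci[0]:.2f} to {100 * acc.spec_ci[1]:.2f})")
# Kappa corrects raw agreement for chance; the exact intervals are wide
# whenever the gold-positive facility count is small.
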