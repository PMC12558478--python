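# facdamage

Rapid health-facility damage reports from remote-sensing building-damage
model outputs.

After a major earthquake, AI models applied to satellite imagery can
estimate building-level damage within days, long before ground-based
engineering surveys finish. `facdamage` turns two common flavors of such
model output into per-facility damage reports for hospitals, dialysis
centers, and pharmacies, and quantifies how much those reports can be
trusted. It is aimed at disaster-response analysts and methods researchers
who need a tested, reproducible implementation of the overlay, aggregation
and evaluation steps — plus a synthetic-city simulator for studying how
known model error modes propagate into facility-level conclusions.

## The methods

Two building-damage dialects are supported:

* **polygon dialect** (model A style): building footprint polygons, each with
  a damaged fraction `d ∈ [0, 1]` — the share of footprint pixels labelled
  damaged. A building is *damaged* iff `d > 0.40` (strict).
* **centroid dialect** (model B style): building centroid points, each with a
  binary class `c ∈ {0, 1}` (1 = major damage/destroyed). A building is
  *damaged* iff `c = 1`.

**Individual overlay.** A facility point is damaged iff it intersects a
damaged footprint, or lies strictly within 25 m of a damaged footprint's
centroid (the *rescue radius*, catching points that fall just outside their
building). For the centroid dialect the facility takes the class of its
nearest centroid within the same radius.

**Spatial aggregation.** Buildings are binned into flat-topped regular
hexagons of fixed area A = 0.125 km² (edge `a = √(2A/3√3) ≈ 219.3 m`). Each
cell's damaged proportion `p = damaged / total` is grouped into quartiles
over non-empty cells; facilities in cells with `p > Q3` are *likely
damaged*.

**Evaluation.** Model-vs-model agreement uses Cohen's kappa
`κ = (p_o − p_e)/(1 − p_e)` with the large-sample standard error
`√(p_o(1−p_o)/(n(1−p_e)²))`. Accuracy against gold-standard labels uses
sensitivity `tp/(tp+fn)` and specificity `tn/(tn+fp)` with exact
Clopper–Pearson binomial intervals, overall and stratified by facility type
and city.

**Synthetic cities.** The simulator generates clustered rectangular
footprints, an exponential-decay damage field centred on an epicenter, typed
facilities with gold labels, and both model dialects with injectable error
modes: polygon merging in dense areas (area-weighted damage dilution),
multi-centroid assignment to large buildings (one per wing), missed
destroyed buildings, and facility geocoding error. Everything is
deterministic given a seed.

## Worked example

```python
from facdamage import (CityParams, ErrorParams, Thresholds, generate_city,
                       overlay_model_a, overlay_model_b, individual_report)

city = generate_city(CityParams(n_buildings=150, bounds=(0, 0, 1200, 1200),
                                n_hospitals=4, n_dialysis=2, n_pharmacies=40),
                     ErrorParams(), seed=11)
calls_a = overlay_model_a(city.facilities, city.model_a, Thresholds())
calls_b = overlay_model_b(city.facilities, city.model_b, Thresholds())
table = individual_report(calls_a, calls_b, city.facilities)
```

Running the bundled scripts (`python examples/02_individual_overlay.py`,
`python examples/04_evaluate_agreement_accuracy.py`) on this city prints:

```
model A: 41 of 46 facilities damaged (89.1%)
model B: 40 of 46 facilities damaged (87.0%)
model agreement: kappa = 0.90 (95% CI 0.70 to 1.00, n = 46)
model A: sensitivity 100.00% (95% CI 91.40 to 100.00), specificity 100.00% (95% CI 47.82 to 100.00)
model B: sensitivity 97.56% (95% CI 87.14 to 99.94), specificity 100.00% (95% CI 47.82 to 100.00)
```

This is a heavily damaged simulated city: 41 of 46 facilities sit on
buildings whose true damaged fraction exceeds 0.40, both dialects recover
nearly all of them under realistic error rates, and the exact intervals are
wide where the gold-negative count is small. The remaining examples cover
simulation (`01`), the hexagonal aggregation (`03`) and a Monte-Carlo sweep
showing sensitivity degrading as destroyed buildings go unrecognized (`05`).

A thin CLI wraps the same functions:

```bash
facdamage simulate --seed 3 --n-buildings 150 --n-hospitals 4 \
    --n-dialysis 2 --n-pharmacies 40 --out city/
facdamage run --model-a city/model_a.geojson --model-b city/model_b.geojson \
    --facilities city/facilities.csv --out report/
```

## Layout

```
src/facdamage/     io, projection, synthetic, overlay, aggregation,
                   evaluation, pipeline, cli
examples/          one short narrative script per capability
tests/             pytest suite with independent brute-force oracles
docs/methods.md    model, parameter and design documentation
```
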