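"""End-to-end orchestration: read -> overlay/aggregate -> evaluate -> report.

`run_pipeline` drives a full run from a single JSON-serializable config and
writes a deterministic report bundle; `run_methods` is the in-memory core
(also used by the synthetic benchmark), producing one call per facility per
model per method.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as fio
from .aggregation import aggregate_damage, facility_cell_calls, make_hex_grid, quartile_classify
from .evaluation import stratified_metrics
from .overlay import individual_report, overlay_model_a, overlay_model_b
from .projection import LocalProjection
from .synthetic import CityParams, ErrorParams, SyntheticCity, generate_city
from .types import (
    Basis,
    FacilityDamageCall,
    HealthFacility,
    Method,
    Model,
    Thresholds,
)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "run_methods", "run_synthetic_benchmark"]


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Paths may be None when a stage is not requested (e.g., no gold labels).
    ``method`` selects the individual overlay, the spatial aggregation, or
    both. ``exclude_no_data`` drops facilities lacking coverage from both
    models before evaluation (the default), rather than keeping them as
    undamaged no-data calls.
    """

    model_a: Optional[str] = None
    model_b: Optional[str] = None
    facilities: Optional[str] = None
    gold: Optional[str] = None
    out: str = "facdamage_out"
    method: str = "both"  # individual | aggregated | both
    thresholds: Thresholds = field(default_factory=Thresholds)
    strata: tuple[str, ...] = ("ftype", "city")
    damage_field: str = "damage_fraction"
    class_field: str = "damage_class"
    exclude_no_data: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.method not in ("individual", "aggregated", "both"):
            raise ValueError(f"unknown method {self.method!r}")
        for name in ("model_a", "model_b", "facilities", "gold"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")
        if self.facilities is None:
            raise ValueError("facilities path is required")
        if self.model_a is None and self.model_b is None:
            raise ValueError("at least one model output is required")


def run_methods(
    facilities: Sequence[HealthFacility],
    model_a_polygons,
    model_b_centroids,
    thresholds: Thresholds = Thresholds(),
    method: str = "both",
    bounds: Optional[tuple[float, float, float, float]] = None,
) -> dict[tuple[Model, Method], list[FacilityDamageCall]]:
    """Produce facility damage calls for the requested methods and models.

    The aggregated method builds one hex grid per model over ``bounds``
    (default: the joint bounding box of that model's buildings and the
    facilities) and computes its quartiles on that model's own building set.
    """
    calls: dict[tuple[Model, Method], list[FacilityDamageCall]] = {}
    if method in ("individual", "both"):
        if model_a_polygons is not None:
            calls[(Model.A, Method.individual)] = overlay_model_a(
                facilities, model_a_polygons, thresholds
            )
        if model_b_centroids is not None:
            calls[(Model.B, Method.individual)] = overlay_model_b(
                facilities, model_b_centroids, thresholds
            )
    if method in ("aggregated", "both"):
        for model, objects in ((Model.A, model_a_polygons), (Model.B, model_b_centroids)):
            if objects is None:
                continue
            b = bounds if bounds is not None else _joint_bounds(objects, facilities)
            grid = make_hex_grid(b, thresholds.cell_area_km2)
            aggregate_damage(objects, grid, thresholds)
            grid, cut = quartile_classify(grid, thresholds.quartile_cut)
            calls[(model, Method.aggregated)] = facility_cell_calls(
                facilities, grid, cut, model
            )
    return calls


def _joint_bounds(objects, facilities) -> tuple[float, float, float, float]:
    xs, ys = [], []
    for o in objects:
        g = getattr(o, "geometry", None)
        if g is not None:
            x0, y0, x1, y1 = g.bounds
            xs += [x0, x1]
            ys += [y0, y1]
        else:
            xs.append(o.location.x)
            ys.append(o.location.y)
    for f in facilities:
        xs.append(f.x)
        ys.append(f.y)
    return (min(xs), min(ys), max(xs), max(ys))


def run_pipeline(config: RunConfig) -> dict:
    """Execute a configured run and write the report bundle.

    Writes per-facility calls, the damage summary table, stratified metrics
    (when gold labels are available), grid layers for the aggregated method,
    and a provenance file. On failure the partially written outputs are
    removed and the failing stage named.
    """
    config.validate()
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run_pipeline_inner(config, outdir, written)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed: {exc}") from exc


def _run_pipeline_inner(config: RunConfig, outdir: Path, written: list[Path]) -> dict:
    thresholds = config.thresholds

    facilities = fio.read_facilities(config.facilities)
    # shared projection for any geographic model inputs
    proj = LocalProjection.from_points(
        [f.lon for f in facilities], [f.lat for f in facilities]
    )
    facilities, removed = fio.deduplicate_facilities(facilities)

    polygons = (
        fio.read_damage_polygons(config.model_a, config.damage_field, proj=proj)
        if config.model_a
        else None
    )
    centroids = (
        fio.read_damage_centroids(config.model_b, config.class_field, proj=proj)
        if config.model_b
        else None
    )

    gold = {f.facility_id: f.gold_label for f in facilities if f.gold_label is not None}
    if config.gold:
        gdf = pd.read_csv(config.gold, dtype={"facility_id": str})
        gold.update(
            {r.facility_id: int(r.gold_label) for r in gdf.itertuples() if pd.notna(r.gold_label)}
        )

    calls = run_methods(facilities, polygons, centroids, thresholds, config.method)

    # exclusion policy: drop facilities lacking coverage from both models
    excluded_ids: set[str] = set()
    if config.exclude_no_data and config.method in ("individual", "both"):
        for key in ((Model.A, Method.individual), (Model.B, Method.individual)):
            for c in calls.get(key, []):
                if c.basis is Basis.no_data:
                    excluded_ids.add(c.facility_id)
    kept = [f for f in facilities if f.facility_id not in excluded_ids]
    calls = {
        k: [c for c in v if c.facility_id not in excluded_ids] for k, v in calls.items()
    }

    all_calls = [c for v in calls.values() for c in v]
    path = outdir / "calls.csv"
    fio.write_calls_csv(all_calls, path)
    written.append(path)

    results: dict = {"n_facilities": len(kept), "n_excluded": len(excluded_ids),
                     "n_duplicates_removed": len(removed)}

    ind_a = calls.get((Model.A, Method.individual))
    ind_b = calls.get((Model.B, Method.individual))
    if ind_a is not None and ind_b is not None:
        summary = individual_report(ind_a, ind_b, kept)
        path = outdir / "summary_table.csv"
        summary.to_csv(path, index=False)
        written.append(path)
        results["summary"] = summary

    strata = {
        kind: {
            f.facility_id: (f.ftype.value if kind == "ftype" else getattr(f, kind))
            for f in kept
        }
        for kind in config.strata
    }
    for method in (Method.individual, Method.aggregated):
        ca = calls.get((Model.A, method))
        cb = calls.get((Model.B, method))
        if ca is None or cb is None:
            continue
        metrics = stratified_metrics(
            {c.facility_id: int(c.damaged) for c in ca},
            {c.facility_id: int(c.damaged) for c in cb},
            gold,
            strata,
            alpha=thresholds.alpha,
        )
        path = outdir / f"metrics_{method.value}.csv"
        metrics.to_csv(path, index=False)
        written.append(path)
        results[f"metrics_{method.value}"] = metrics

    damaged_ids = {c.facility_id for c in all_calls if c.damaged}
    fio.write_geojson(
        [f.location for f in kept if f.facility_id in damaged_ids],
        [
            {"facility_id": f.facility_id, "name": f.name, "ftype": f.ftype.value}
            for f in kept
            if f.facility_id in damaged_ids
        ],
        outdir / "damaged_facilities.geojson",
    )
    written.append(outdir / "damaged_facilities.geojson")

    prov = {
        "config": {
            **{k: v for k, v in asdict(config).items() if k != "thresholds"},
            "thresholds": asdict(thresholds),
        },
        "projection": proj.describe(),
        "excluded_no_data": sorted(excluded_ids),
        "duplicates_removed": removed,
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(prov, fh, indent=2, sort_keys=True)
    written.append(outdir / "provenance.json")
    results["provenance"] = prov
    return results


# ---------------------------------------------------------------------------
# synthetic benchmark


def evaluate_synthetic_city(
    city: SyntheticCity,
    thresholds: Thresholds = Thresholds(),
    method: str = "both",
) -> dict:
    """Sensitivity/specificity per model and method, plus A-vs-B kappa,
    on one synthetic city with known gold labels."""
    from .evaluation import cohens_kappa, confusion, sens_spec

    gold = {f.facility_id: f.gold_label for f in city.facilities}
    calls = run_methods(
        city.facilities, city.model_a, city.model_b, thresholds, method,
        bounds=city.bounds,
    )
    out: dict = {}
    for method_enum in (Method.individual, Method.aggregated):
        ca = calls.get((Model.A, method_enum))
        cb = calls.get((Model.B, method_enum))
        if ca is None:
            continue
        for model, cc in (("a", ca), ("b", cb)):
            table, _ = confusion({c.facility_id: int(c.damaged) for c in cc}, gold)
            acc = sens_spec(table, thresholds.alpha)
            out[f"sens_{model}_{method_enum.value}"] = acc.sensitivity
            out[f"spec_{model}_{method_enum.value}"] = acc.specificity
        agr = cohens_kappa(
            [int(c.damaged) for c in ca], [int(c.damaged) for c in cb], thresholds.alpha
        )
        out[f"kappa_{method_enum.value}"] = agr.kappa if agr.defined else float("nan")
    return out


def run_synthetic_benchmark(
    error_grid: Sequence[ErrorParams],
    n_seeds: int = 20,
    city_params: CityParams = CityParams(),
    thresholds: Thresholds = Thresholds(),
    method: str = "both",
    base_seed: int = 0,
) -> pd.DataFrame:
    """Monte-Carlo benchmark over an error-parameter grid.

    For each error configuration and seed, generates a city and computes
    sensitivity/specificity for both models and kappa for both methods.
    Returns the per-seed table; summarize with groupby means and standard
    errors.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    rows = []
    for gi, err in enumerate(error_grid):
        for s in range(n_seeds):
            seed = int(np.random.SeedSequence([base_seed, gi, s]).generate_state(1)[0] % (2**31))
            city = generate_city(city_params, err, seed)
            res = evaluate_synthetic_city(city, thresholds, method)
            rows.append({"grid_index": gi, **asdict(err), "seed": seed, **res})
    return pd.DataFrame(rows)


def summarize_benchmark(bench: pd.DataFrame) -> pd.DataFrame:
    """Mean and Monte-Carlo standard error per error configuration."""
    metrics = [c for c in bench.columns
               if c.startswith(("sens_", "spec_", "kappa_"))]
    g = bench.groupby("grid_index")[metrics]
    mean = g.mean()
    se = g.sem()
    se.columns = [f"{c}_se" for c in se.columns]
    return mean.join(se).reset_index()
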