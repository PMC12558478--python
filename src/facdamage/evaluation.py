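"""Agreement and accuracy statistics for facility damage calls.

Two models' binary calls are compared with Cohen's kappa (chance-corrected
agreement); calls are validated against gold-standard labels with
sensitivity and specificity carrying exact Clopper–Pearson binomial
confidence intervals. All statistics are available pooled and stratified by
facility type and city.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "ConfusionTable",
    "AgreementResult",
    "AccuracyResult",
    "confusion",
    "clopper_pearson",
    "sens_spec",
    "cohens_kappa",
    "stratified_metrics",
]


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class AgreementResult:
    """Cohen's kappa with its asymptotic standard error and Wald CI.

    ``kappa`` is None (flagged undefined) when expected agreement is 1,
    i.e., both raters are constant.
    """

    kappa: Optional[float]
    se: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    n: int
    po: float
    pe: float

    @property
    def defined(self) -> bool:
        return self.kappa is not None


@dataclass(frozen=True)
class AccuracyResult:
    sensitivity: Optional[float]
    specificity: Optional[float]
    sens_ci: Optional[tuple[float, float]]
    spec_ci: Optional[tuple[float, float]]
    table: ConfusionTable
    alpha: float


def confusion(
    calls: Mapping[str, int], gold: Mapping[str, int]
) -> tuple[ConfusionTable, list[str]]:
    """2x2 counts of binary calls against gold labels, keyed by facility id.

    Facilities missing a gold label (or absent from ``gold``) are excluded
    and returned in the exclusion list. Raises if no facility has both a
    call and a gold label.
    """
    excluded = []
    tp = fp = fn = tn = 0
    for fid, call in calls.items():
        g = gold.get(fid)
        if g is None:
            excluded.append(fid)
            continue
        call, g = int(call), int(g)
        if call not in (0, 1) or g not in (0, 1):
            raise ValueError(f"non-binary call/gold for facility {fid!r}")
        if g == 1:
            tp += call
            fn += 1 - call
        else:
            fp += call
            tn += 1 - call
    table = ConfusionTable(tp, fp, fn, tn)
    if table.n == 0:
        raise ValueError("no facility has both a call and a gold label")
    if excluded:
        log.info("confusion: excluded %d facilities without gold labels", len(excluded))
    return table, excluded


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact central binomial (Clopper–Pearson) confidence interval.

    The bounds invert the binomial tail probabilities at ``alpha/2`` per
    side, expressed through beta quantiles: the lower bound is the
    ``alpha/2`` quantile of Beta(k, n-k+1) (0 when k = 0) and the upper the
    ``1 - alpha/2`` quantile of Beta(k+1, n-k) (1 when k = n).
    """
    if not (0 <= k <= n) or n < 1:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


def sens_spec(table: ConfusionTable, alpha: float = 0.05) -> AccuracyResult:
    """Sensitivity and specificity with exact binomial intervals.

    Sensitivity = tp/(tp+fn): the share of truly damaged facilities the
    model flags; specificity = tn/(tn+fp). An estimate with a zero
    denominator is returned as None (flagged undefined), never raised.
    """
    npos = table.tp + table.fn
    nneg = table.tn + table.fp
    sens = table.tp / npos if npos else None
    spec = table.tn / nneg if nneg else None
    if npos == 0 or nneg == 0:
        log.warning("sens_spec: empty gold class (pos=%d, neg=%d); estimate undefined", npos, nneg)
    return AccuracyResult(
        sensitivity=sens,
        specificity=spec,
        sens_ci=clopper_pearson(table.tp, npos, alpha) if npos else None,
        spec_ci=clopper_pearson(table.tn, nneg, alpha) if nneg else None,
        table=table,
        alpha=alpha,
    )


def cohens_kappa(
    x: Sequence[int], y: Sequence[int], alpha: float = 0.05
) -> AgreementResult:
    """Cohen's kappa between two paired binary raters.

    kappa = (po - pe) / (1 - pe), with po the observed agreement fraction
    and pe the chance agreement from the marginal distributions. The
    standard error is the large-sample approximation
    ``sqrt(po (1 - po) / (n (1 - pe)^2))`` and the CI is the normal Wald
    interval truncated to [-1, 1]. When both raters are constant (pe = 1)
    kappa is undefined and flagged, never silently 0 or 1.
    """
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-d vectors of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 paired calls")
    if not (np.isin(x, (0, 1)).all() and np.isin(y, (0, 1)).all()):
        raise ValueError("calls must be binary")

    po = float(np.mean(x == y))
    px1, py1 = float(np.mean(x)), float(np.mean(y))
    pe = px1 * py1 + (1 - px1) * (1 - py1)
    if pe >= 1.0 - 1e-15:
        return AgreementResult(None, None, None, None, n, po, pe)
    kappa = (po - pe) / (1 - pe)
    se = float(np.sqrt(po * (1 - po) / (n * (1 - pe) ** 2)))
    z = float(stats.norm.ppf(1 - alpha / 2))
    return AgreementResult(
        kappa=kappa,
        se=se,
        ci_low=max(-1.0, kappa - z * se),
        ci_high=min(1.0, kappa + z * se),
        n=n,
        po=po,
        pe=pe,
    )


def cohens_kappa_bootstrap(
    x: Sequence[int], y: Sequence[int], alpha: float = 0.05,
    n_boot: int = 2000, seed: int = 0,
) -> AgreementResult:
    """Alternative kappa CI by nonparametric pair resampling (percentile)."""
    base = cohens_kappa(x, y, alpha)
    if not base.defined:
        return base
    rng = np.random.default_rng(seed)
    x = np.asarray(x, int)
    y = np.asarray(y, int)
    n = x.size
    reps = []
    for _ in range(n_boot):
        i = rng.integers(0, n, size=n)
        r = cohens_kappa(x[i], y[i], alpha)
        if r.defined:
            reps.append(r.kappa)
    lo, hi = np.percentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return AgreementResult(base.kappa, base.se, float(lo), float(hi), n, base.po, base.pe)


def stratified_metrics(
    calls_a: Mapping[str, int],
    calls_b: Mapping[str, int],
    gold: Mapping[str, Optional[int]],
    strata: Mapping[str, Mapping[str, str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Agreement and accuracy per stratum plus pooled.

    ``strata`` maps stratum kind (e.g., ``ftype``, ``city``) to a mapping
    facility_id -> label. Output has one row per (kind, label) and one
    pooled row; strata where kappa is undefined are flagged, not dropped.
    Accuracy columns are filled only where gold labels exist in the stratum.
    """
    common = sorted(set(calls_a) & set(calls_b))
    if set(calls_a) != set(calls_b):
        raise ValueError("model A and B call sets must cover the same facilities")

    def one(ids: list[str], kind: str, label: str) -> dict:
        xa = [int(calls_a[i]) for i in ids]
        xb = [int(calls_b[i]) for i in ids]
        row: dict = {"stratum": kind, "label": label, "n": len(ids)}
        if len(ids) >= 2:
            agr = cohens_kappa(xa, xb, alpha)
            row.update(
                kappa=agr.kappa, kappa_se=agr.se,
                kappa_ci_low=agr.ci_low, kappa_ci_high=agr.ci_high,
                kappa_defined=agr.defined, po=agr.po, pe=agr.pe,
            )
        with_gold = {i: gold[i] for i in ids if gold.get(i) is not None}
        if with_gold:
            for model, calls in (("a", calls_a), ("b", calls_b)):
                table, _ = confusion({i: calls[i] for i in with_gold}, with_gold)
                acc = sens_spec(table, alpha)
                row[f"sens_{model}"] = acc.sensitivity
                row[f"spec_{model}"] = acc.specificity
                if acc.sens_ci:
                    row[f"sens_{model}_ci_low"], row[f"sens_{model}_ci_high"] = acc.sens_ci
                if acc.spec_ci:
                    row[f"spec_{model}_ci_low"], row[f"spec_{model}_ci_high"] = acc.spec_ci
        return row

    rows = [one(common, "pooled", "all")]
    for kind, labels in strata.items():
        unknown = set(labels) - set(common)
        values = sorted({labels[i] for i in common if i in labels})
        missing = [i for i in common if i not in labels]
        if missing:
            raise KeyError(f"stratum {kind!r} lacks labels for {missing[:5]}")
        del unknown
        for v in values:
            ids = [i for i in common if labels[i] == v]
            rows.append(one(ids, kind, v))
    return pd.DataFrame(rows)
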