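"""Degree-based sampling weights and population prevalence estimators."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "PrevalenceEstimate",
    "rds2_weights",
    "naive_prevalence",
    "rds2_prevalence",
    "rds1_prevalence",
    "prevalence_interval",
]

Z95 = 1.959963984540054


@dataclass(frozen=True)
class PrevalenceEstimate:
    estimator: str
    point: float
    se: float
    ci_low: float
    ci_high: float
    method: str = "wald"
    meta: dict = field(default_factory=dict)

    @property
    def ci(self) -> tuple[float, float]:
        return self.ci_low, self.ci_high


def rds2_weights(degrees) -> np.ndarray:
    """Volz-Heckathorn inverse-degree weights, normalized to mean one.

    ``w_i = (1/d_i) / mean_j(1/d_j)`` so that ``sum(w) == n``.  Scale-free in
    the degrees: multiplying every degree by a constant leaves w unchanged.
    """
    d = np.asarray(degrees, dtype=float)
    if np.any(d <= 0):
        raise ValueError("all degrees must be >= 1")
    inv = 1.0 / d
    return inv / inv.mean()


def _truncate(lo: float, hi: float) -> tuple[float, float]:
    return max(lo, 0.0), min(hi, 1.0)


def _wald(point: float, se: float) -> tuple[float, float]:
    return _truncate(point - Z95 * se, point + Z95 * se)


def naive_prevalence(sample) -> PrevalenceEstimate:
    """Unweighted sample proportion in G1 with a Wald interval."""
    y = np.asarray(sample.table["group"], dtype=float)
    p = float(y.mean())
    se = float(np.sqrt(p * (1 - p) / len(y)))
    lo, hi = _wald(p, se)
    return PrevalenceEstimate("naive", p, se, lo, hi)


def _hajek(y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Hajek ratio estimate and its linearized (sandwich) SE."""
    sw = w.sum()
    p = float((w * y).sum() / sw)
    # linearization: var = sum(w_i^2 (y_i - p)^2) / (sum w)^2
    se = float(np.sqrt(np.sum(w**2 * (y - p) ** 2)) / sw)
    return p, se


def rds2_prevalence(sample) -> PrevalenceEstimate:
    """RDS-II (Volz-Heckathorn) prevalence: Hajek ratio with 1/d weights."""
    t = sample.table
    y = np.asarray(t["group"], dtype=float)
    w = rds2_weights(t["degree"].to_numpy())
    p, se = _hajek(y, w)
    lo, hi = _wald(p, se)
    return PrevalenceEstimate("rds2", p, se, lo, hi, method="design_robust")


def rds1_prevalence(sample) -> PrevalenceEstimate:
    """RDS-I (Salganik-Heckathorn) reciprocity estimator.

    Combines the cross-group recruitment proportions with the groups'
    (harmonic) mean degrees:

        P1 = C21 * D2 / (C12 * D1 + C21 * D2)

    where ``Cab`` is the proportion of group-a recruiters' recruits that are
    in group b, and ``Da`` the harmonic mean degree of group a (the
    reciprocity / multiplicity form of the estimator).
    """
    t = sample.table
    outcome_by_id = dict(zip(t["id"], t["group"]))
    recruits = t[t["wave"] > 0]
    if recruits.empty:
        raise ValueError("no recruiter-recruit pairs in sample")
    rec_y = recruits["recruiter_id"].map(outcome_by_id).to_numpy()
    y = recruits["group"].to_numpy()
    n1_from_1 = int(((rec_y == 1) & (y == 1)).sum())
    n2_from_1 = int(((rec_y == 1) & (y == 0)).sum())
    n1_from_2 = int(((rec_y == 0) & (y == 1)).sum())
    n2_from_2 = int(((rec_y == 0) & (y == 0)).sum())
    total_1 = n1_from_1 + n2_from_1
    total_2 = n1_from_2 + n2_from_2
    if n1_from_2 == 0 and n2_from_1 == 0:
        raise ValueError("no cross-group recruitments; RDS-I undefined")
    # data-smoothed cross-recruitment proportions
    c12 = n2_from_1 / total_1 if total_1 else 0.0
    c21 = n1_from_2 / total_2 if total_2 else 0.0
    d = t["degree"].to_numpy().astype(float)
    g = t["group"].to_numpy()
    d1 = len(d[g == 1]) / np.sum(1.0 / d[g == 1]) if (g == 1).any() else np.nan
    d2 = len(d[g == 0]) / np.sum(1.0 / d[g == 0]) if (g == 0).any() else np.nan
    denom = c12 * d1 + c21 * d2
    if not np.isfinite(denom) or denom == 0:
        raise ValueError("degenerate RDS-I estimate")
    p = float(c21 * d2 / denom)
    # no analytic SE in the reciprocity form; report the naive binomial scale
    se = float(np.sqrt(max(p * (1 - p), 0.0) / len(t)))
    lo, hi = _wald(p, se)
    return PrevalenceEstimate("rds1", p, se, lo, hi, method="reciprocity",
                              meta={"c12": c12, "c21": c21, "d1": d1, "d2": d2})


def weighted_logistic_prevalence(sample, weighted: bool = True) -> PrevalenceEstimate:
    """Survey-style intercept-only logistic prevalence with robust SE.

    With RDS-II weights this is the weighted survey estimator; without, the
    unweighted one.  The point estimate is the (weighted) mean outcome; the
    SE is the linearized design-robust variance of the Hajek ratio.
    """
    t = sample.table
    y = np.asarray(t["group"], dtype=float)
    w = rds2_weights(t["degree"].to_numpy()) if weighted else np.ones(len(y))
    p, se = _hajek(y, w)
    lo, hi = _wald(p, se)
    name = "weighted_logistic" if weighted else "unweighted_logistic"
    return PrevalenceEstimate(name, p, se, lo, hi, method="design_robust")


def prevalence_interval(
    sample,
    estimator: Literal["naive", "rds2", "rds1", "weighted_logistic",
                       "unweighted_logistic"] = "naive",
    method: Literal["wald", "design_robust", "salganik_bootstrap"] = "wald",
    n_boot: int = 1000,
    rng=None,
) -> PrevalenceEstimate:
    """95% interval for a prevalence estimator by the requested method."""
    compute = {
        "naive": naive_prevalence,
        "rds2": rds2_prevalence,
        "rds1": rds1_prevalence,
        "weighted_logistic": lambda s: weighted_logistic_prevalence(s, True),
        "unweighted_logistic": lambda s: weighted_logistic_prevalence(s, False),
    }[estimator]
    est = compute(sample)
    if method in ("wald", "design_robust"):
        return est
    # salganik bootstrap: resample whole recruitment chains with replacement
    rng = np.random.default_rng(rng)
    t = sample.table
    chains = t["seed_id"].unique()
    meta = dict(est.meta)
    if len(chains) < 2:
        meta["warning"] = "single recruitment chain; bootstrap unreliable"
    points = []
    for _ in range(n_boot):
        picked = rng.choice(chains, size=len(chains), replace=True)
        boot = pd.concat([t[t["seed_id"] == c] for c in picked], ignore_index=True)
        try:
            points.append(compute(type(sample)(table=boot)).point)
        except ValueError:
            continue
    lo, hi = np.percentile(points, [2.5, 97.5])
    lo, hi = _truncate(float(lo), float(hi))
    return PrevalenceEstimate(
        est.estimator, est.point, float(np.std(points, ddof=1)), lo, hi,
        method="salganik_bootstrap", meta=meta,
    )
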