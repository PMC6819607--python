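"""Monte-Carlo reduction of fit results to study metrics.

Four metrics per model variant: type-I error (null-predictor fits), CI
coverage against the full-population parameter, relative bias of the
exponentiated slope (mean and median), and in-sample prediction accuracy.
Accuracy is only reported for models passing the validity gate
(error <= 0.05 and coverage >= 0.95).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .models import FitResult, ModelSpec, prepare_regression_data
from .netpop import PopulationParameters

__all__ = [
    "EvaluationSummary",
    "type1_error",
    "coverage",
    "relative_bias",
    "prediction_accuracy",
    "summarize_fits",
    "summarize_study",
    "ACCURACY_GATE_ERROR",
    "ACCURACY_GATE_COVERAGE",
]

ACCURACY_GATE_ERROR = 0.05
ACCURACY_GATE_COVERAGE = 0.95


@dataclass(frozen=True)
class EvaluationSummary:
    model: str
    population: str  # population id or "pooled"
    type1_error: float
    coverage: float
    bias_mean_pct: float
    bias_median_pct: float
    accuracy_pct: float | None  # None when the validity gate fails
    n_converged_null: int
    n_converged_predict: int


def _converged(fits: Iterable[FitResult]) -> list[FitResult]:
    return [f for f in fits if f.converged]


def type1_error(null_fits: Iterable[FitResult]) -> float:
    """Fraction of converged null-predictor fits with p <= 0.05."""
    fits = _converged(null_fits)
    if not fits:
        raise ValueError("no converged fits")
    return float(np.mean([f.p_value <= 0.05 for f in fits]))


def _truth_for(fit: FitResult, truth: PopulationParameters) -> float:
    if fit.spec.family == "binomial_logit":
        return truth.odds_ratio
    return truth.relative_risk


def coverage(
    predict_fits: Iterable[FitResult],
    truths: PopulationParameters | Sequence[PopulationParameters],
) -> float:
    """Fraction of converged fits whose exponentiated 95% CI contains truth.

    ``truths`` is either one PopulationParameters or a sequence aligned with
    the fits (one per replicate, for pooled evaluation over populations).
    """
    fits = list(predict_fits)
    if isinstance(truths, PopulationParameters):
        truths = [truths] * len(fits)
    hits = []
    for f, t in zip(fits, truths, strict=True):
        if not f.converged:
            continue
        lo, hi = f.exp_ci
        hits.append(lo <= _truth_for(f, t) <= hi)
    if not hits:
        raise ValueError("no converged fits")
    return float(np.mean(hits))


def relative_bias(
    predict_fits: Iterable[FitResult],
    truths: PopulationParameters | Sequence[PopulationParameters],
    center: str = "mean",
) -> float:
    """100 * (center(theta_hat) - theta) / theta on the exponentiated scale.

    With per-replicate truths the ratio theta_hat/theta is centered instead,
    which coincides with the plain formula for a single truth.
    """
    fits = list(predict_fits)
    if isinstance(truths, PopulationParameters):
        truths = [truths] * len(fits)
    ratios = [
        f.exp_slope / _truth_for(f, t)
        for f, t in zip(fits, truths, strict=True)
        if f.converged
    ]
    if not ratios:
        raise ValueError("no converged fits")
    c = np.mean(ratios) if center == "mean" else np.median(ratios)
    return float(100.0 * (c - 1.0))


def prediction_accuracy(fit_params, frame: pd.DataFrame, spec: ModelSpec) -> float:
    """Percent of observations whose outcome the fitted model predicts.

    ``fit_params`` are the link-scale coefficients; fitted means are
    thresholded at 0.5 for both families.
    """
    from .models import _design  # shared design construction

    X = _design(frame, spec)
    eta = X @ np.asarray(fit_params)
    with np.errstate(over="ignore"):  # saturated fits classify correctly anyway
        if spec.family == "binomial_logit":
            p = 1.0 / (1.0 + np.exp(-eta))
        else:
            p = np.exp(eta)
    g = frame["y"].to_numpy()
    correct = ((p >= 0.5) & (g == 1)) | ((p < 0.5) & (g == 0))
    return float(100.0 * correct.mean())


def summarize_fits(
    model: str,
    population: str,
    null_fits: Sequence[FitResult],
    predict_fits: Sequence[FitResult],
    truths: PopulationParameters | Sequence[PopulationParameters],
    accuracies: Sequence[float] | None = None,
) -> EvaluationSummary:
    """Reduce one model's replicates (for one population or pooled)."""
    err = type1_error(null_fits)
    cov = coverage(predict_fits, truths)
    acc: float | None = None
    if accuracies and err <= ACCURACY_GATE_ERROR and cov >= ACCURACY_GATE_COVERAGE:
        acc = float(np.mean(accuracies))
    return EvaluationSummary(
        model=model,
        population=population,
        type1_error=err,
        coverage=cov,
        bias_mean_pct=relative_bias(predict_fits, truths, "mean"),
        bias_median_pct=relative_bias(predict_fits, truths, "median"),
        accuracy_pct=acc,
        n_converged_null=len(_converged(null_fits)),
        n_converged_predict=len(_converged(predict_fits)),
    )


def summarize_study(
    results: pd.DataFrame,
    truths: dict[str, PopulationParameters],
) -> pd.DataFrame:
    """Per-population and pooled summary table from a long results frame.

    ``results`` columns: population, replicate, model, family, predictor,
    slope, se, p_value, converged, exp_slope, ci_low_exp, ci_high_exp,
    accuracy (NaN for null fits).
    """
    rows = []
    pops = sorted(results["population"].unique())
    models = list(dict.fromkeys(results["model"]))

    def reduce(sub: pd.DataFrame, pop_label: str, model: str) -> None:
        nulls = sub[sub["predictor"] == "X_NULL"]
        preds = sub[sub["predictor"] == "X_predict"]
        cn = nulls["converged"]
        cp = preds["converged"]
        if cn.sum() == 0 or cp.sum() == 0:
            return
        err = float((nulls.loc[cn, "p_value"] <= 0.05).mean())
        truth_vals = np.array(
            [
                truths[p].odds_ratio if fam == "binomial_logit" else truths[p].relative_risk
                for p, fam in zip(preds["population"], preds["family"])
            ]
        )
        okp = preds.loc[cp]
        tv = truth_vals[cp.to_numpy()]
        cov = float(((okp["ci_low_exp"] <= tv) & (tv <= okp["ci_high_exp"])).mean())
        ratios = okp["exp_slope"].to_numpy() / tv
        acc_vals = okp["accuracy"].dropna()
        gate = err <= ACCURACY_GATE_ERROR and cov >= ACCURACY_GATE_COVERAGE
        rows.append(
            {
                "population": pop_label,
                "model": model,
                "type1_error": err,
                "coverage": cov,
                "bias_mean_pct": 100 * (ratios.mean() - 1),
                "bias_median_pct": 100 * (np.median(ratios) - 1),
                "accuracy_pct": float(acc_vals.mean()) if gate and len(acc_vals) else np.nan,
                "n_converged_null": int(cn.sum()),
                "n_converged_predict": int(cp.sum()),
            }
        )

    for model in models:
        msub = results[results["model"] == model]
        for pop in pops:
            reduce(msub[msub["population"] == pop], pop, model)
        reduce(msub, "pooled", model)
    return pd.DataFrame(rows)
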