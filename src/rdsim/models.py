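"""Regression model battery for RDS samples.

Each :class:`ModelSpec` names one regression variant: a family (logit-link
binomial or log-link Poisson), optional inverse-degree (RDS-II) weighting,
a clustering control, and a variance estimator.  Fitting returns the slope
of the chosen predictor with a Wald 95% CI on the link scale (and
exponentiated), a two-sided p-value and a convergence flag.

Weighted fits use mean-one normalized weights entering the score and the
information matrix as frequency-style multipliers; the model-based SE of a
weighted fit is the inverse weighted information.  Survey-style robust SEs
for weighted fits are obtained by combining ``weighting="rds2"`` with a
sandwich variance instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .estimators import rds2_weights
from .sampler import RDSSample

__all__ = [
    "ModelSpec",
    "FitResult",
    "SingleClusterError",
    "prepare_regression_data",
    "fit_glm",
    "fit_gee",
    "fit_model",
    "sandwich_variance",
    "run_model_battery",
    "HEADLINE_BATTERY",
]

Family = Literal["binomial_logit", "poisson_log"]
Weighting = Literal["none", "rds2"]
Clustering = Literal[
    "none",
    "recruiter_outcome_covariate",
    "gee_independence_recruiter",
    "gee_exchangeable_recruiter",
    "gee_ar1_chain",
    "glmm_seed_intercept",  # optional scope; not implemented
]
Variance = Literal[
    "model_based",
    "sandwich_classical",
    "sandwich_firores",
    "sandwich_firoeeq",
    "sandwich_mbn",
]

_GEE_CLUSTERINGS = {
    "gee_independence_recruiter",
    "gee_exchangeable_recruiter",
    "gee_ar1_chain",
}


class SingleClusterError(ValueError):
    """Cluster-robust variance undefined with a single cluster."""


@dataclass(frozen=True)
class ModelSpec:
    family: Family = "binomial_logit"
    weighting: Weighting = "none"
    clustering: Clustering = "none"
    variance: Variance = "model_based"
    label: str = ""

    def __post_init__(self) -> None:
        if self.clustering in _GEE_CLUSTERINGS and self.variance == "model_based":
            raise ValueError("GEE clustering requires a sandwich variance")

    @property
    def name(self) -> str:
        return self.label or (
            f"{self.family}/{self.weighting}/{self.clustering}/{self.variance}"
        )


@dataclass(frozen=True)
class FitResult:
    spec: ModelSpec
    predictor: str
    slope: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    converged: bool
    n_used: int
    params: tuple[float, ...] = ()  # full link-scale coefficient vector

    @property
    def exp_slope(self) -> float:
        return float(np.exp(self.slope))

    @property
    def exp_ci(self) -> tuple[float, float]:
        with np.errstate(over="ignore"):  # inf upper limit is a valid CI end
            return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))


_FAILED = dict(slope=np.nan, se=np.nan, ci_low=np.nan, ci_high=np.nan,
               p_value=np.nan, converged=False)


def _statsmodels_family(family: Family):
    if family == "binomial_logit":
        return sm.families.Binomial()
    if family == "poisson_log":
        return sm.families.Poisson()
    raise ValueError(f"unknown family {family!r}")


def prepare_regression_data(
    sample: RDSSample, predictor: str, spec: ModelSpec
) -> pd.DataFrame:
    """Build the model frame: seeds dropped, weights/clusters attached.

    Seeds (wave 0) are excluded so every row has an observed recruiter
    outcome.  Weights are RDS-II weights computed on the retained rows.
    """
    if predictor not in ("X_predict", "X_NULL"):
        raise ValueError(f"unknown predictor {predictor!r}")
    t = sample.table
    outcome_by_id = dict(zip(t["id"], t["group"]))
    frame = t[t["wave"] > 0].copy()
    if frame.empty:
        raise ValueError("no non-seed rows to fit on")
    frame = frame.rename(columns={"group": "y", predictor: "x"})
    frame["recruiter_y"] = frame["recruiter_id"].map(outcome_by_id)
    if spec.weighting == "rds2":
        frame["weight"] = rds2_weights(frame["degree"].to_numpy())
    cols = ["y", "x", "recruiter_y", "recruiter_id", "seed_id", "wave", "degree"]
    if "weight" in frame:
        cols.append("weight")
    return frame[cols].reset_index(drop=True)


def _design(frame: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    cols = [np.ones(len(frame)), frame["x"].to_numpy()]
    if spec.clustering == "recruiter_outcome_covariate":
        cols.append(frame["recruiter_y"].to_numpy())
    return np.column_stack(cols)


def _weights(frame: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    if spec.weighting == "rds2":
        return frame["weight"].to_numpy()
    return np.ones(len(frame))


def _clusters(frame: pd.DataFrame, cluster_def: str) -> np.ndarray:
    if cluster_def == "observation":
        return np.arange(len(frame))
    if cluster_def == "recruiter":
        return frame["recruiter_id"].to_numpy()
    if cluster_def == "seed":
        return frame["seed_id"].to_numpy()
    raise ValueError(f"unknown cluster definition {cluster_def!r}")


def _result_from_params(
    spec: ModelSpec, predictor: str, params, cov, converged: bool, n: int
) -> FitResult:
    from scipy import stats

    slope = float(params[1])
    se = float(np.sqrt(cov[1, 1]))
    if not converged or not np.isfinite(se) or se <= 0:
        return FitResult(spec=spec, predictor=predictor, n_used=n, **_FAILED)
    z = slope / se
    return FitResult(
        spec=spec,
        predictor=predictor,
        slope=slope,
        se=se,
        ci_low=slope - 1.959963984540054 * se,
        ci_high=slope + 1.959963984540054 * se,
        p_value=float(2 * stats.norm.sf(abs(z))),
        converged=True,
        n_used=n,
        params=tuple(float(v) for v in np.asarray(params)),
    )


def fit_glm(frame: pd.DataFrame, spec: ModelSpec, predictor: str = "x") -> FitResult:
    """Fit a (possibly weighted) GLM; model-based or sandwich SE per spec."""
    if spec.clustering in _GEE_CLUSTERINGS:
        raise ValueError("use fit_gee for GEE clustering controls")
    X = _design(frame, spec)
    y = frame["y"].to_numpy().astype(float)
    w = _weights(frame, spec)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(y, X, family=_statsmodels_family(spec.family), freq_weights=w)
            res = model.fit(tol=1e-12)
        converged = bool(res.converged)
    except Exception:
        return FitResult(spec=spec, predictor=predictor, n_used=len(frame), **_FAILED)
    # model-based covariance recomputed as the exact inverse weighted
    # information at the converged parameters (statsmodels' pinv-based path
    # agrees only to ~1e-7)
    *_, info = _glm_pieces(res.params, frame, spec)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.asarray(res.cov_params())
    fit = _result_from_params(spec, predictor, res.params, cov, converged, len(frame))
    if spec.variance != "model_based" and fit.converged:
        cluster_def = "recruiter" if spec.clustering != "none" else "observation"
        flavor = spec.variance.removeprefix("sandwich_")
        cov = sandwich_variance(
            params=res.params, frame=frame, spec=spec,
            cluster_def=cluster_def, flavor=flavor,
        )
        fit = _result_from_params(spec, predictor, res.params, cov, True, len(frame))
    return fit


def _glm_pieces(params, frame: pd.DataFrame, spec: ModelSpec):
    """Mean, variance function and weighted score/information pieces."""
    X = _design(frame, spec)
    y = frame["y"].to_numpy().astype(float)
    w = _weights(frame, spec)
    eta = X @ params
    if spec.family == "binomial_logit":
        mu = 1.0 / (1.0 + np.exp(-eta))
        v = mu * (1.0 - mu)
    else:
        mu = np.exp(eta)
        v = mu
    # canonical links: score_i = w_i * (y_i - mu_i) * x_i ; info = X' diag(w v) X
    scores = (w * (y - mu))[:, None] * X
    info = X.T @ (X * (w * v)[:, None])
    return X, y, w, mu, v, scores, info


def sandwich_variance(
    params,
    frame: pd.DataFrame,
    spec: ModelSpec,
    cluster_def: str = "recruiter",
    flavor: str = "classical",
) -> np.ndarray:
    """Cluster-robust sandwich covariance for a fitted GLM.

    flavors:
      classical -- Huber-White: B (sum_c s_c s_c') B with B the inverse
        information (bread) and s_c the summed score of cluster c.
      firores   -- residual-corrected: cluster scores are inflated by
        (I - H_cc)^{-1} where H_cc = X_c B X_c' W_c is the cluster leverage
        (Mancl-DeRouen style correction).
      firoeeq   -- estimating-equation corrected: scores scaled by
        (1 - min(q, h_c))^{-1/2} with h_c = trace(H_cc)/p and q = 0.75
        (Fay-Graubard style correction).
      mbn       -- Morel-Bokossa-Neerchal: classical meat inflated by
        k/(k-1) * (n-1)/(n-p) plus an additive phi*delta*B ridge term.
    """
    X, y, w, mu, v, scores, info = _glm_pieces(params, frame, spec)
    bread = np.linalg.inv(info)
    clusters = _clusters(frame, cluster_def)
    labels, inverse = np.unique(clusters, return_inverse=True)
    k = len(labels)
    if k < 2:
        raise SingleClusterError("need >= 2 clusters for a sandwich variance")
    n, p = X.shape

    cluster_scores = np.zeros((k, p))
    if flavor in ("classical", "mbn"):
        np.add.at(cluster_scores, inverse, scores)
    elif flavor == "firores":
        for c in range(k):
            idx = inverse == c
            Xc = X[idx]
            wc = (w * v)[idx]
            Hc = Xc @ bread @ (Xc * wc[:, None]).T
            rc = (w * (y - mu))[idx]
            cluster_scores[c] = Xc.T @ np.linalg.solve(np.eye(idx.sum()) - Hc, rc)
    elif flavor == "firoeeq":
        q = 0.75
        for c in range(k):
            idx = inverse == c
            Xc = X[idx]
            wc = (w * v)[idx]
            Hc = Xc @ bread @ (Xc * wc[:, None]).T
            hc = float(np.trace(Hc)) / p
            scale = 1.0 / np.sqrt(max(1.0 - min(q, hc), 1e-12))
            cluster_scores[c] = scale * scores[idx].sum(axis=0)
    else:
        raise ValueError(f"unknown sandwich flavor {flavor!r}")

    meat = cluster_scores.T @ cluster_scores
    cov = bread @ meat @ bread
    if flavor == "mbn":
        if k > p:
            c_adj = (k / (k - 1)) * ((n - 1) / (n - p))
            delta = min(0.5, p / (k - p))
            phi = max(1.0, float(np.trace(bread @ meat)) * c_adj / p)
            cov = c_adj * cov + delta * phi * bread
        else:
            cov = cov * (k / max(k - 1, 1))
    return cov


def fit_gee(frame: pd.DataFrame, spec: ModelSpec, predictor: str = "x") -> FitResult:
    """Fit a GEE with the working correlation implied by the clustering."""
    if spec.clustering not in _GEE_CLUSTERINGS:
        raise ValueError("fit_gee requires a gee_* clustering")
    X = _design(frame, spec)
    y = frame["y"].to_numpy().astype(float)
    w = _weights(frame, spec)

    if spec.clustering == "gee_ar1_chain":
        groups = frame["seed_id"].to_numpy()
        time = frame["wave"].to_numpy()[:, None]
        cov_structs = [sm.cov_struct.Autoregressive(grid=False),
                       sm.cov_struct.Independence()]  # fallback, flagged
    else:
        groups = frame["recruiter_id"].to_numpy()
        time = None
        if spec.clustering == "gee_exchangeable_recruiter":
            cov_structs = [sm.cov_struct.Exchangeable()]
        else:
            cov_structs = [sm.cov_struct.Independence()]

    res = None
    for cov_struct in cov_structs:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.GEE(
                    y, X, groups=groups, time=time,
                    family=_statsmodels_family(spec.family),
                    cov_struct=cov_struct,
                    weights=w if spec.weighting == "rds2" else None,
                )
                res = model.fit()
            break
        except Exception:
            res = None
    if res is None:
        return FitResult(spec=spec, predictor=predictor, n_used=len(frame), **_FAILED)
    converged = bool(getattr(res, "converged", True))

    if spec.variance in ("sandwich_classical",):
        cov = np.asarray(res.cov_params())  # statsmodels default: robust sandwich
    elif spec.variance == "sandwich_firores":
        try:
            cov = np.asarray(res.cov_robust_bc)  # Mancl-DeRouen bias-reduced
        except Exception:
            cov = np.asarray(res.cov_params())
    else:
        # firoeeq / mbn: apply the GLM-score machinery at the GEE estimate
        # with an independence working model (documented approximation)
        cluster_def = "seed" if spec.clustering == "gee_ar1_chain" else "recruiter"
        cov = sandwich_variance(
            res.params, frame, spec,
            cluster_def=cluster_def,
            flavor=spec.variance.removeprefix("sandwich_"),
        )
    return _result_from_params(spec, predictor, res.params, cov, converged, len(frame))


def fit_model(frame: pd.DataFrame, spec: ModelSpec, predictor: str = "x") -> FitResult:
    if spec.clustering == "glmm_seed_intercept":
        raise NotImplementedError("seed-intercept GLMM is optional scope")
    if spec.clustering in _GEE_CLUSTERINGS:
        return fit_gee(frame, spec, predictor)
    return fit_glm(frame, spec, predictor)


# The four headline variants (unweighted/weighted x binomial/Poisson GLM).
HEADLINE_BATTERY: tuple[ModelSpec, ...] = (
    ModelSpec("binomial_logit", "none", label="glm_binomial"),
    ModelSpec("binomial_logit", "rds2", label="glm_binomial_rds2"),
    ModelSpec("poisson_log", "none", label="glm_poisson"),
    ModelSpec("poisson_log", "rds2", label="glm_poisson_rds2"),
)


def run_model_battery(
    sample: RDSSample,
    specs: Iterable[ModelSpec] = HEADLINE_BATTERY,
    predictors: tuple[str, ...] = ("X_NULL", "X_predict"),
) -> dict[tuple[str, str], FitResult]:
    """Fit every spec once per predictor; keyed by (spec name, predictor)."""
    out: dict[tuple[str, str], FitResult] = {}
    for spec in specs:
        for predictor in predictors:
            frame = prepare_regression_data(sample, predictor, spec)
            out[(spec.name, predictor)] = fit_model(frame, spec, predictor)
    return out
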