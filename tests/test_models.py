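import numpy as np
import pandas as pd
import pytest

from rdsim.models import (
    HEADLINE_BATTERY,
    ModelSpec,
    SingleClusterError,
    fit_gee,
    fit_glm,
    fit_model,
    prepare_regression_data,
    run_model_battery,
    sandwich_variance,
)


def make_frame(n=20, seed=0, clusters=None, weights=None):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    eta = -0.5 + 0.8 * x
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    frame = pd.DataFrame(
        {
            "y": y,
            "x": x,
            "recruiter_y": 0.0,
            "recruiter_id": clusters if clusters is not None else np.arange(n),
            "seed_id": clusters if clusters is not None else np.arange(n),
            "wave": np.ones(n, dtype=int),
            "degree": rng.integers(1, 50, size=n),
        }
    )
    if weights is not None:
        frame["weight"] = weights
    return frame


def irls_oracle(y, X, w, family, tol=1e-12):
    """Independent Newton-Raphson for canonical-link GLMs with weights."""
    beta = np.zeros(X.shape[1])
    for _ in range(200):
        eta = X @ beta
        if family == "binomial_logit":
            mu = 1 / (1 + np.exp(-eta))
            v = mu * (1 - mu)
        else:
            mu = np.exp(eta)
            v = mu
        score = X.T @ (w * (y - mu))
        info = X.T @ (X * (w * v)[:, None])
        step = np.linalg.solve(info, score)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return beta, se


class TestFitGlm:
    @pytest.mark.parametrize("family", ["binomial_logit", "poisson_log"])
    def test_matches_newton_raphson_oracle(self, family):
        rng = np.random.default_rng(4)
        frame = make_frame(n=20, seed=1, weights=rng.uniform(0.2, 3.0, 20))
        frame["weight"] /= frame["weight"].mean()
        spec = ModelSpec(family, "rds2")
        fit = fit_glm(frame, spec)
        X = np.column_stack([np.ones(len(frame)), frame["x"]])
        beta, se = irls_oracle(
            frame["y"].to_numpy(), X, frame["weight"].to_numpy(), family
        )
        assert fit.slope == pytest.approx(beta[1], abs=1e-8)
        assert fit.se == pytest.approx(se[1], abs=1e-8)

    @pytest.mark.parametrize("c", [1.0, 0.5, 7.0])
    def test_constant_weights_reproduce_unweighted_fit(self, c):
        frame = make_frame(n=40, seed=2)
        unweighted = fit_glm(frame, ModelSpec("binomial_logit", "none"))
        frame["weight"] = np.full(len(frame), c) / c  # mean-one normalization
        weighted = fit_glm(frame, ModelSpec("binomial_logit", "rds2"))
        assert weighted.slope == pytest.approx(unweighted.slope, abs=1e-10)
        assert weighted.se == pytest.approx(unweighted.se, abs=1e-10)

    def test_wald_inference_fields(self):
        fit = fit_glm(make_frame(n=60, seed=3), ModelSpec("binomial_logit", "none"))
        assert fit.converged
        assert fit.ci_low == pytest.approx(fit.slope - 1.96 * fit.se, abs=1e-3)
        assert np.exp(fit.ci_low) == pytest.approx(fit.exp_ci[0])
        assert 0 <= fit.p_value <= 1

    def test_family_slope_signs_agree(self):
        frame = make_frame(n=200, seed=5)
        b = fit_glm(frame, ModelSpec("binomial_logit", "none"))
        p = fit_glm(frame, ModelSpec("poisson_log", "none"))
        assert np.sign(b.slope) == np.sign(p.slope) == 1.0

    def test_leverage_of_low_degree_point(self):
        # one extreme-x G2 observation with degree 1 (huge weight) must move
        # the weighted slope strictly more than the unweighted slope
        frame = make_frame(n=60, seed=8)
        frame["degree"] = 20
        base_u = fit_glm(frame, ModelSpec("binomial_logit", "none")).slope
        extra = frame.iloc[[0]].copy()
        extra["y"] = 0.0
        extra["x"] = 4.0
        extra["degree"] = 1
        frame2 = pd.concat([frame, extra], ignore_index=True)
        from rdsim.estimators import rds2_weights

        frame2["weight"] = rds2_weights(frame2["degree"].to_numpy())
        u = fit_glm(frame2, ModelSpec("binomial_logit", "none")).slope
        w = fit_glm(frame2, ModelSpec("binomial_logit", "rds2")).slope
        assert abs(w - base_u) > abs(u - base_u)

    def test_gee_clustering_rejected(self):
        with pytest.raises(ValueError, match="fit_gee"):
            fit_glm(make_frame(), ModelSpec(
                "binomial_logit", "none", "gee_exchangeable_recruiter",
                "sandwich_classical",
            ))

    def test_glmm_not_implemented(self):
        with pytest.raises(NotImplementedError):
            fit_model(make_frame(), ModelSpec(
                "binomial_logit", "none", "glmm_seed_intercept", "model_based"
            ))


class TestPrepareRegressionData:
    def test_seed_exclusion_arithmetic(self, sample30):
        spec = ModelSpec("binomial_logit", "none")
        frame = prepare_regression_data(sample30, "X_predict", spec)
        n_seeds = (sample30.table["wave"] == 0).sum()
        assert len(frame) == sample30.n - n_seeds

    def test_recruiter_outcome_attached(self, sample30):
        spec = ModelSpec("binomial_logit", "none", "recruiter_outcome_covariate")
        frame = prepare_regression_data(sample30, "X_predict", spec)
        outcome = dict(zip(sample30.table["id"], sample30.table["group"]))
        for row in frame.sample(25, random_state=0).itertuples():
            assert row.recruiter_y == outcome[row.recruiter_id]

    def test_no_weight_column_when_unweighted(self, sample30):
        frame = prepare_regression_data(
            sample30, "X_NULL", ModelSpec("binomial_logit", "none")
        )
        assert "weight" not in frame.columns

    def test_weights_mean_one_over_frame(self, sample30):
        frame = prepare_regression_data(
            sample30, "X_NULL", ModelSpec("binomial_logit", "rds2")
        )
        assert frame["weight"].mean() == pytest.approx(1.0)

    def test_unknown_predictor(self, sample30):
        with pytest.raises(ValueError):
            prepare_regression_data(sample30, "X_wrong", ModelSpec())


def brute_force_sandwich(params, frame, spec, cluster_def="recruiter"):
    """Direct matrix computation: B (sum_c s_c s_c') B."""
    X = np.column_stack([np.ones(len(frame)), frame["x"]])
    y = frame["y"].to_numpy()
    w = frame["weight"].to_numpy() if spec.weighting == "rds2" else np.ones(len(frame))
    eta = X @ np.asarray(params)
    if spec.family == "binomial_logit":
        mu = 1 / (1 + np.exp(-eta))
        v = mu * (1 - mu)
    else:
        mu = np.exp(eta)
        v = mu
    info = sum(
        w[i] * v[i] * np.outer(X[i], X[i]) for i in range(len(frame))
    )
    bread = np.linalg.inv(info)
    key = "recruiter_id" if cluster_def == "recruiter" else "seed_id"
    meat = np.zeros((2, 2))
    for _, sub in frame.groupby(key):
        idx = sub.index.to_numpy()
        s = sum(w[i] * (y[i] - mu[i]) * X[i] for i in idx)
        meat += np.outer(s, s)
    return bread @ meat @ bread


class TestSandwichVariance:
    def test_classical_equals_brute_force_on_toy_clusters(self):
        clusters = np.repeat([0, 1, 2], 7)
        frame = make_frame(n=21, seed=10, clusters=clusters)
        spec = ModelSpec("binomial_logit", "none")
        fit = fit_glm(frame, spec)
        cov = sandwich_variance(np.array(fit.params), frame, spec,
                                cluster_def="recruiter", flavor="classical")
        expected = brute_force_sandwich(fit.params, frame, spec)
        assert np.allclose(cov, expected, atol=1e-10)

    def test_classical_brute_force_weighted_poisson(self):
        rng = np.random.default_rng(0)
        clusters = np.repeat([0, 1, 2, 3, 4], 5)
        frame = make_frame(n=25, seed=11, clusters=clusters,
                           weights=rng.uniform(0.5, 2.0, 25))
        spec = ModelSpec("poisson_log", "rds2")
        fit = fit_glm(frame, spec)
        cov = sandwich_variance(np.array(fit.params), frame, spec,
                                cluster_def="recruiter", flavor="classical")
        expected = brute_force_sandwich(fit.params, frame, spec)
        assert np.allclose(cov, expected, atol=1e-10)

    def test_mbn_at_least_classical(self):
        clusters = np.repeat(np.arange(8), 5)
        frame = make_frame(n=40, seed=12, clusters=clusters)
        spec = ModelSpec("binomial_logit", "none")
        fit = fit_glm(frame, spec)
        args = (np.array(fit.params), frame, spec)
        classical = sandwich_variance(*args, cluster_def="recruiter",
                                      flavor="classical")
        mbn = sandwich_variance(*args, cluster_def="recruiter", flavor="mbn")
        assert mbn[1, 1] >= classical[1, 1]

    @pytest.mark.parametrize("flavor", ["firores", "firoeeq"])
    def test_small_sample_corrections_inflate(self, flavor):
        clusters = np.repeat(np.arange(5), 6)
        frame = make_frame(n=30, seed=13, clusters=clusters)
        spec = ModelSpec("binomial_logit", "none")
        fit = fit_glm(frame, spec)
        args = (np.array(fit.params), frame, spec)
        classical = sandwich_variance(*args, cluster_def="recruiter",
                                      flavor="classical")
        corrected = sandwich_variance(*args, cluster_def="recruiter", flavor=flavor)
        assert corrected[1, 1] > classical[1, 1]

    def test_observation_clusters_consistent_with_model_se(self):
        frame = make_frame(n=4000, seed=14)
        spec = ModelSpec("binomial_logit", "none")
        fit = fit_glm(frame, spec)
        cov = sandwich_variance(np.array(fit.params), frame, spec,
                                cluster_def="observation", flavor="classical")
        assert 0.9 < np.sqrt(cov[1, 1]) / fit.se < 1.1

    def test_single_cluster_error(self):
        frame = make_frame(n=10, seed=15, clusters=np.zeros(10, dtype=int))
        spec = ModelSpec("binomial_logit", "none")
        fit = fit_glm(frame, spec)
        with pytest.raises(SingleClusterError):
            sandwich_variance(np.array(fit.params), frame, spec,
                              cluster_def="recruiter", flavor="classical")


class TestFitGee:
    def test_independence_matches_glm_point_estimate(self):
        clusters = np.repeat(np.arange(10), 4)
        frame = make_frame(n=40, seed=20, clusters=clusters)
        glm = fit_glm(frame, ModelSpec("binomial_logit", "none"))
        gee = fit_gee(frame, ModelSpec(
            "binomial_logit", "none", "gee_independence_recruiter",
            "sandwich_classical",
        ))
        assert gee.slope == pytest.approx(glm.slope, abs=1e-6)

    def test_exchangeable_singleton_clusters_reduce_to_glm_sandwich(self):
        frame = make_frame(n=50, seed=21)  # every row its own cluster
        glm_spec = ModelSpec("binomial_logit", "none")
        glm = fit_glm(frame, glm_spec)
        gee = fit_gee(frame, ModelSpec(
            "binomial_logit", "none", "gee_exchangeable_recruiter",
            "sandwich_classical",
        ))
        assert gee.slope == pytest.approx(glm.slope, abs=1e-6)
        cov = sandwich_variance(np.array(glm.params), frame, glm_spec,
                                cluster_def="recruiter", flavor="classical")
        assert gee.se == pytest.approx(np.sqrt(cov[1, 1]), rel=0.05)

    def test_exchangeable_solves_estimating_equations(self):
        # oracle: at the fitted working correlation, the weighted GEE score
        # must vanish — checked by explicit per-cluster matrix algebra
        import statsmodels.api as sm

        clusters = np.repeat(np.arange(6), 5)
        frame = make_frame(n=30, seed=22, clusters=clusters)
        spec = ModelSpec("binomial_logit", "none", "gee_exchangeable_recruiter",
                         "sandwich_classical")
        gee = fit_gee(frame, spec)
        model = sm.GEE(
            frame["y"].to_numpy(),
            np.column_stack([np.ones(len(frame)), frame["x"]]),
            groups=frame["recruiter_id"].to_numpy(),
            family=sm.families.Binomial(),
            cov_struct=sm.cov_struct.Exchangeable(),
        )
        res = model.fit()
        alpha = float(res.cov_struct.dep_params)
        beta = np.asarray(res.params)
        X = np.column_stack([np.ones(len(frame)), frame["x"]])
        y = frame["y"].to_numpy()
        score = np.zeros(2)
        for c in np.unique(clusters):
            idx = clusters == c
            Xc, yc = X[idx], y[idx]
            mu = 1 / (1 + np.exp(-(Xc @ beta)))
            A = np.diag(mu * (1 - mu))
            m = idx.sum()
            R = np.full((m, m), alpha) + (1 - alpha) * np.eye(m)
            D = A @ Xc  # dmu/dbeta for canonical logit
            V = np.sqrt(A) @ R @ np.sqrt(A)
            score += D.T @ np.linalg.solve(V, yc - mu)
        assert np.max(np.abs(score)) < 1e-4
        assert gee.slope == pytest.approx(beta[1], abs=1e-8)

    def test_ar1_chain_runs_and_infers(self, sample30):
        spec = ModelSpec("binomial_logit", "none", "gee_ar1_chain",
                         "sandwich_classical")
        frame = prepare_regression_data(sample30, "X_predict", spec)
        fit = fit_gee(frame, spec)
        assert fit.converged
        assert fit.se > 0

    def test_gee_requires_sandwich(self):
        with pytest.raises(ValueError, match="sandwich"):
            ModelSpec("binomial_logit", "none", "gee_exchangeable_recruiter",
                      "model_based")


class TestRunModelBattery:
    def test_bookkeeping(self, sample30):
        out = run_model_battery(sample30)
        assert len(out) == 2 * len(HEADLINE_BATTERY)
        labels = {k[0] for k in out}
        assert labels == {
            "glm_binomial", "glm_binomial_rds2", "glm_poisson", "glm_poisson_rds2",
        }

    def test_headline_battery_composition(self):
        fams = {(s.family, s.weighting) for s in HEADLINE_BATTERY}
        assert fams == {
            ("binomial_logit", "none"), ("binomial_logit", "rds2"),
            ("poisson_log", "none"), ("poisson_log", "rds2"),
        }

    def test_determinism(self, sample30):
        a = run_model_battery(sample30)
        b = run_model_battery(sample30)
        for k in a:
            assert a[k].slope == b[k].slope
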