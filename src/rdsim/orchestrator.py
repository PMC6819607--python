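"""End-to-end study runner: populations -> samples -> fits -> summaries.

Reproduces the primary (3 prevalences x 4 homophilies) and secondary
(4 degree-outcome-correlation modes x 2 homophilies) experiments at
configurable scale from one config with full seed provenance: a root seed
spawns one stream per population, which spawns one stream per replicate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
import numpy as np
import pandas as pd

from . import __version__
from .estimators import naive_prevalence, rds2_prevalence, weighted_logistic_prevalence
from .evaluation import prediction_accuracy, summarize_study
from .models import HEADLINE_BATTERY, ModelSpec, fit_model, prepare_regression_data
from .netpop import (
    DEFAULT_DEGREE_SPEC,
    DegreeDistributionSpec,
    NetworkedPopulation,
    build_correlated_population,
    build_population,
    population_parameters,
)
from .sampler import SamplerConfig, rds_sample

__all__ = ["StudyConfig", "run_primary_study", "run_secondary_study"]

PRESET_REPLICATES = {"smoke": 5, "desk": 250, "full": 1000}

PRIMARY_GRID = [(pi, hx) for pi in (0.10, 0.30, 0.50) for hx in (1.0, 1.1, 1.25, 1.5)]
SECONDARY_GRID = [
    (mode, hx)
    for hx in (1.25, 1.5)
    for mode in ("extreme_neg", "extreme_pos", "moderate_neg", "moderate_pos")
]


@dataclass
class StudyConfig:
    preset: str = "desk"
    n_population: int = 10_000
    replicates: int | None = None  # overrides the preset count
    root_seed: int = 0
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    battery: tuple[ModelSpec, ...] = HEADLINE_BATTERY
    degree_spec: DegreeDistributionSpec = DEFAULT_DEGREE_SPEC
    output_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.preset not in PRESET_REPLICATES:
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.replicates is None:
            self.replicates = PRESET_REPLICATES[self.preset]
        if self.preset == "smoke" and self.replicates > 10:
            raise ValueError("smoke preset is capped at 10 replicates")

    @property
    def n_replicates(self) -> int:
        assert self.replicates is not None
        return self.replicates


def _population_label(key) -> str:
    if isinstance(key[0], float):
        return f"pi{int(round(key[0] * 100))}_hx{key[1]:g}"
    return f"{key[0]}_hx{key[1]:g}"


def _replicate_results(
    pop: NetworkedPopulation,
    label: str,
    config: StudyConfig,
    pop_ss: np.random.SeedSequence,
) -> list[dict]:
    adj = pop.adjacency()
    rows: list[dict] = []
    for rep, child in enumerate(pop_ss.spawn(config.n_replicates)):
        rng = np.random.default_rng(child)
        sample = rds_sample(pop, config.sampler, rng, adjacency=adj)
        prev = {
            "naive": naive_prevalence(sample),
            "rds2": rds2_prevalence(sample),
            "unweighted_logistic": weighted_logistic_prevalence(sample, False),
            "weighted_logistic": weighted_logistic_prevalence(sample, True),
        }
        for spec in config.battery:
            for predictor in ("X_NULL", "X_predict"):
                frame = prepare_regression_data(sample, predictor, spec)
                fit = fit_model(frame, spec, predictor)
                acc = np.nan
                if fit.converged and predictor == "X_predict":
                    acc = prediction_accuracy(fit.params, frame, spec)
                lo, hi = fit.exp_ci if fit.converged else (np.nan, np.nan)
                rows.append(
                    {
                        "population": label,
                        "replicate": rep,
                        "model": spec.name,
                        "family": spec.family,
                        "predictor": predictor,
                        "slope": fit.slope,
                        "se": fit.se,
                        "p_value": fit.p_value,
                        "converged": fit.converged,
                        "exp_slope": fit.exp_slope if fit.converged else np.nan,
                        "ci_low_exp": lo,
                        "ci_high_exp": hi,
                        "accuracy": acc,
                        "sample_waves": sample.waves,
                        "n_reseeds": sample.n_reseeds,
                    }
                )
        for name, est in prev.items():
            rows.append(
                {
                    "population": label,
                    "replicate": rep,
                    "model": f"prevalence_{name}",
                    "family": "prevalence",
                    "predictor": "",
                    "slope": est.point,
                    "se": est.se,
                    "p_value": np.nan,
                    "converged": True,
                    "exp_slope": np.nan,
                    "ci_low_exp": est.ci_low,
                    "ci_high_exp": est.ci_high,
                    "accuracy": np.nan,
                    "sample_waves": sample.waves,
                    "n_reseeds": sample.n_reseeds,
                }
            )
    return rows


def _write_outputs(
    outdir: Path,
    config: StudyConfig,
    pop_table: pd.DataFrame,
    results: pd.DataFrame,
    summary: pd.DataFrame,
    prevalence: pd.DataFrame,
    name: str,
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    pop_table.to_csv(outdir / f"{name}_populations.csv", index=False)
    results.to_csv(outdir / f"{name}_fits.csv", index=False)
    summary.to_csv(outdir / f"{name}_summary.csv", index=False)
    prevalence.to_csv(outdir / f"{name}_prevalence.csv", index=False)
    manifest = {
        "study": name,
        "version": __version__,
        "preset": config.preset,
        "replicates": config.n_replicates,
        "root_seed": config.root_seed,
        "sampler": asdict(config.sampler),
        "battery": [s.name for s in config.battery],
        "n_population": config.n_population,
        "n_nonconverged": int((~results["converged"]).sum()),
    }
    (outdir / f"{name}_manifest.json").write_text(json.dumps(manifest, indent=2))


def _prevalence_summary(results: pd.DataFrame, pop_table: pd.DataFrame) -> pd.DataFrame:
    prev = results[results["family"] == "prevalence"].copy()
    truth = dict(zip(pop_table["population"], pop_table["pi"]))
    prev["truth"] = prev["population"].map(truth)
    prev["covered"] = (prev["ci_low_exp"] <= prev["truth"]) & (
        prev["truth"] <= prev["ci_high_exp"]
    )
    out = (
        prev.groupby(["population", "model"])
        .agg(
            mean_estimate=("slope", "mean"),
            sd_estimate=("slope", "std"),
            coverage=("covered", "mean"),
        )
        .reset_index()
    )
    return out


def run_primary_study(config: StudyConfig) -> dict:
    """12-population grid: Table 1/2/3 analogues."""
    ss = np.random.SeedSequence(config.root_seed)
    pop_streams = ss.spawn(len(PRIMARY_GRID))
    all_rows: list[dict] = []
    pop_records = []
    truths = {}
    for (pi, hx), pop_ss in zip(PRIMARY_GRID, pop_streams):
        label = _population_label((pi, hx))
        build_ss, sample_ss = pop_ss.spawn(2)
        pop = build_population(
            pi, hx, spec=config.degree_spec,
            rng=np.random.default_rng(build_ss), n=config.n_population,
        )
        params = population_parameters(pop)
        truths[label] = params
        pop_records.append(
            {
                "population": label,
                "pi": pi,
                "hx": hx,
                "odds_ratio": params.odds_ratio,
                "relative_risk": params.relative_risk,
                "realized_hx": pop.realized_hx,
                "omega": pop.omega,
                "t_ii": pop.t_ii,
                "t_ij": pop.t_ij,
            }
        )
        all_rows.extend(_replicate_results(pop, label, config, sample_ss))
    results = pd.DataFrame(all_rows)
    fit_rows = results[results["family"] != "prevalence"]
    pop_table = pd.DataFrame(pop_records)
    summary = summarize_study(fit_rows, truths)
    prevalence = _prevalence_summary(results, pop_table)
    if config.output_dir is not None:
        _write_outputs(
            Path(config.output_dir), config, pop_table, results, summary,
            prevalence, "primary",
        )
    return {
        "populations": pop_table,
        "results": results,
        "summary": summary,
        "prevalence": prevalence,
        "truths": truths,
    }


def run_secondary_study(config: StudyConfig) -> dict:
    """8 degree-outcome-correlated populations: Table 4 analogue."""
    ss = np.random.SeedSequence(config.root_seed + 1)
    pop_streams = ss.spawn(len(SECONDARY_GRID))
    all_rows: list[dict] = []
    pop_records = []
    truths = {}
    for (mode, hx), pop_ss in zip(SECONDARY_GRID, pop_streams):
        label = _population_label((mode, hx))
        build_ss, sample_ss = pop_ss.spawn(2)
        pop = build_correlated_population(
            mode, hx, spec=config.degree_spec,
            rng=np.random.default_rng(build_ss), n=config.n_population,
        )
        params = population_parameters(pop)
        truths[label] = params
        pop_records.append(
            {
                "population": label,
                "mode": mode,
                "pi": pop.pi,
                "hx": hx,
                "rho": pop.rho,
                "odds_ratio": params.odds_ratio,
                "relative_risk": params.relative_risk,
                "realized_hx_stub": pop.meta.get("realized_hx_stub"),
                "omega": pop.omega,
            }
        )
        all_rows.extend(_replicate_results(pop, label, config, sample_ss))
    results = pd.DataFrame(all_rows)
    fit_rows = results[results["family"] != "prevalence"]
    pop_table = pd.DataFrame(pop_records)
    summary = summarize_study(fit_rows, truths)
    # Table 4 analogue: type-I error per population x model, with rho
    errs = summary[summary["population"] != "pooled"][
        ["population", "model", "type1_error"]
    ].merge(pop_table[["population", "mode", "hx", "rho"]], on="population")
    prevalence = _prevalence_summary(results, pop_table)
    if config.output_dir is not None:
        out = Path(config.output_dir)
        _write_outputs(out, config, pop_table, results, summary, prevalence, "secondary")
        errs.to_csv(out / "secondary_error_table.csv", index=False)
    return {
        "populations": pop_table,
        "results": results,
        "summary": summary,
        "error_table": errs,
        "truths": truths,
    }
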