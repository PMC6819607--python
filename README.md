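# rdsim

A simulation-and-evaluation pipeline for studying the validity of regression
on respondent-driven sampling (RDS) data.

The pipeline generates homophily-controlled networked populations with a
calibrated multimodal degree distribution, draws RDS samples (seeds, coupons,
non-response, no repeat recruitment), fits weighted and unweighted binomial
and Poisson regression variants with various clustering controls and sandwich
variance estimators, and measures type-I error, confidence-interval coverage,
relative bias, prediction accuracy and prevalence-estimator performance by
Monte Carlo.

## Modules

| module | role |
| --- | --- |
| `rdsim.netpop` | networked populations: degree mixture, exact-prevalence groups, homophily tie quotas, grouped configuration-model wiring, full-population "truth" parameters |
| `rdsim.sampler` | RDS recruitment forests: uniform seeds, 3 coupons, 50% per-offer response, mid-wave truncation, reseeding of dead chains |
| `rdsim.estimators` | Volz–Heckathorn (RDS-II) inverse-degree weights; naive / RDS-I / RDS-II / survey-style prevalence estimators with Wald, design-robust and chain-bootstrap intervals |
| `rdsim.models` | GLM / GEE battery: logit and log links, optional RDS-II weighting, recruiter-outcome covariate, exchangeable/independence/AR(1)-by-wave working correlations; classical, FIRORES-, FIROEEQ- and MBN-style sandwich variances |
| `rdsim.evaluation` | type-I error, coverage, mean/median relative bias, gated prediction accuracy; per-population and pooled summary tables |
| `rdsim.orchestrator` | primary (12-population) and secondary (8 correlated-degree population) studies with seed provenance and CSV/JSON outputs |

## CLI

```sh
rdsim generate-population --pi 0.3 --hx 1.25 --seed 1 --out pop/
rdsim sample --population pop/ --seed 2 --out sample.csv
rdsim sampling-correlation --population pop/ --n-samples 1000
rdsim run-primary  --preset desk --seed 1 --out results/primary/
rdsim run-secondary --preset desk --seed 1 --out results/secondary/
```

Presets: `smoke` (≤10 replicates, integration checks), `desk` (250),
`full` (1000, the original protocol scale).

## Notes on calibration

The exact degree-generating mixture behind the reference study is not
published. The default `DegreeDistributionSpec` is a frozen binomial mixture
calibrated so the exact mixture pmf has median 20 and mean 47.5, visible
modes near 10/20/50/100, a high-degree tail, and a low-degree continuum that
reproduces the leverage-driven failure of inverse-degree-weighted regression
(inflated type-I error and degraded coverage) while unweighted regression
stays near nominal. Quantities that depend on finer details of the original
distribution (the exact weighted error magnitude, the Table 4 correlation
values, the sampling-frequency correlation) track the reference results
qualitatively but can differ in the second decimal.
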