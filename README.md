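# behavnet

Laboratory-free risk analysis for incident type 2 diabetes (T2DM) from
behavioral, psychosocial and dietary cohort data — and a systems-level view
of how the relationships among those behaviors reorganize in the disease
state.

The package is aimed at epidemiologists and quantitative health researchers
working with tabular survival cohorts (one row per participant, typed
covariates, an event indicator and follow-up time in years). It implements
two complementary analytic frameworks end to end, plus a synthetic-cohort
generator with known ground truth so every stage is testable without access
to any restricted data source.

## The two frameworks

**1. Cox risk scoring and stratification.** The hazard of T2DM onset is
modeled as

    h(t | X) = h0(t) · exp(β₁X₁ + β₂X₂ + … + β_pX_p)

with dummy-coded behavioral predictors (psychosocial and sleep flags,
smoking history, dietary frequencies and types, age and BMI categories).
Model development follows standard practice: univariate screening
(p < 0.05), low-variance and VIF (> 10) filters, a jointly fitted
L2-penalized model with iterative backward refinement, Schoenfeld-residual
proportional-hazards diagnostics with covariate×time interactions for
violators, and 10-fold stratified cross-validated concordance. Each
participant's risk score is the linear predictor Σ βⱼxᵢⱼ; a five-leaf
decision tree on score vs observed incidence freezes four cutpoints
defining *very low* … *very high* strata, validated with Kaplan–Meier
curves, pairwise log-rank tests and survival-time percentiles (with an ∞
sentinel for percentiles never reached).

**2. ANN effective-weight influence networks.** For every variable in turn,
a two-hidden-layer feedforward network (ReLU, 64 and 32 units) predicts that
variable from all the others. The systemic influence of input *i* on output
*o* is the sum over all hidden paths of the product of connection weights,

    W_eff[i,o] = Σ_{h1} Σ_{h2}  w[i,h1] · w[h1,h2] · w[h2,o],

aggregated as the median over a 10-run × 5-fold ensemble, with *sign
stability* (the share of ensemble members agreeing on the sign) tiered as
highly stable (≥ 70%), moderately stable (60–69%), low stability (< 60%) or
unstable (≈ 50/50). Per-cohort influence matrices are compared by
subtraction (disease-state minus healthy); sign reversals mark reorganized
relationships. Positive influences define a directed network whose
in-/out-degree, eigenvector, betweenness and PageRank centralities — and
their healthy→disease shifts — combine with hazard ratios to classify each
variable as a *dual-priority target*, *structural stabilizer*, *emergent
driver* or *other*.

## Worked example

`examples/03_survival_risk_model.py` simulates a 3,000-participant cohort,
fits the Cox pipeline and stratifies risk. It prints (abridged):

```
23 terms survive the univariate screen
final model: 16 terms; PH violations: ['cereal_type[muesli]']

hazard table (head):
                  term  beta   hr  hr_pct        p  ci_low  ci_high
  loneliness_isolation  0.23 1.26    26.0 0.000140    1.12     1.41
sleeplessness_insomnia  0.16 1.17    17.0 0.004248    1.05     1.31
   sleep_duration_7_8h -0.12 0.88   -12.0 0.026151    0.79     0.99

worked risk scores: protective profile -0.55, high-risk profile 0.91

stratum score ranges and observed incidence:
  very_low   [ -0.84,  -0.04]  incidence 0.24
  low        [ -0.03,   0.19]  incidence 0.31
  moderate   [  0.20,   0.56]  incidence 0.46
  high       [  0.57,   0.93]  incidence 0.57
  very_high  [  0.94,   1.70]  incidence 0.75

pairwise log-rank: 10 tests, smallest p = 3.28e-50
```

Reading the numbers: each hazard-table row gives the log-hazard coefficient,
the hazard ratio exp(β), the percent change in hazard (HR%), and its 95% CI —
loneliness here raises the instantaneous T2DM hazard by 26%. The worked
profiles show how the linear predictor combines coefficients: a lonely,
well-slept muesli eater scores 0.13 − 0.13 − 0.55 = −0.55 (*very low*
stratum of the reference stratification), while loneliness + daytime napping
+ current smoking + sugary cereal + age 60–70 gives 0.13 + 0.09 + 0.17 +
0.10 + 0.42 = 0.91 (*high*). Observed incidence rises monotonically across
the derived strata and every pairwise log-rank test separates them.

The other scripts in `examples/` each demonstrate one capability:
cohort simulation (01), the cleaning/outlier-removal chain (02), influence
matrices on a planted toy system (04), cohesion networks and role
classification (05), and the full pipeline with artifacts and manifest (06).

## Command line

```bash
behavnet simulate --n 1000 --seed 13 --out cohort.csv --schema schema.json
behavnet run --config config.json          # full pipeline
behavnet report <run_dir>                  # regenerate the markdown report
```

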