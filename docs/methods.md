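# Methods

This note documents the models behind `behavnet`, the defaults and why they
were chosen, the numerical conventions, and what the synthetic-data studies
do and do not demonstrate.

## Synthetic cohort generator

**Covariates.** The default schema has 19 variables mirroring a
laboratory-free behavioral T2DM model: ten binary psychosocial/sleep/
gaming/smoking flags plus binary cheese intake, a three-level smoking
history (never/previous/current), four-level ordinal added salt, nominal
bread (reference wholewheat) and cereal (reference bran) types, six-level
processed-meat and beef frequency scales (reference never), and continuous
age (40–70 y) and BMI (18.5–50 kg/m²). Level probabilities are plausible
population defaults and make no claim to match any particular cohort's
marginals; they are tunable per `VariableSpec`.

**Dependence structure.** Variables are tied together by a Gaussian copula
over two latent behavioral factors: a *distress* factor loading on the
psychosocial/sleep/lifestyle variables and a *diet-quality* factor loading
on the dietary variables and BMI (loadings in
`simulate.DEFAULT_FACTOR_MAP`; `latent_correlation`, default 0.8, scales
them globally and 0 restores full independence). The distress factor is a
balanced two-component normal mixture (centers ±1.2, within-component SD
0.3), giving the pooled standardized data the two-cluster geometry that
population behavioral data typically shows and that the unsupervised
outlier pipeline presupposes. Marginals are preserved *exactly* despite the
non-normal factor: each variable's latent normal is pushed through the
closed-form CDF of its own latent mixture before quantile mapping.

**Event times.** Survival times follow a Weibull-baseline proportional-
hazards model, S(t|x) = exp(−(t/s)^k · e^lp), sampled by inverse transform.
Defaults: shape k = 1.2 (gently rising baseline hazard typical of adult-
onset chronic disease) and scale s = 50 years, calibrated once from the
closed form so a high-risk profile (linear predictor ≈ 0.9) has ≈ 50%
cumulative event probability by the 17-year administrative cutoff. The
default coefficient vector is the reference coefficient set
(`reference.REFERENCE_BETAS`); dummy levels without a reference coefficient
(the rare "daily" meat levels) default to 0. Times below one year are
resampled so follow-up spans [1, 17] years. Non-events are censored at the
minimum of a uniform [1, 17] censoring time (last-assessment style) and the
cutoff. Event rows are labeled `t2dm`, censored rows `healthy`; the healthy
stream carries a 20% surplus so cleaning can drop rows and still
down-sample healthy to the T2DM size.

**Missingness.** A configurable fraction of rows receives > 20% missing
schema cells (so the row filter has work to do); the rest receive sparse
cell-level missingness. A share of categorical missing cells is written as
integer special codes (−1 "don't know", −3 "prefer not to answer") instead
of blanks, exercising the recoding stage.

**Ground-truth outliers.** Corrupted rows are regenerated from latent
factors placed on a ring 3.2–5 within-component (Mahalanobis) SDs from the
row's parent mixture component — an improbable joint behavioral profile
along the population's own dependence structure — with halved residual
noise, plus a shift of every continuous field by ~8 marginal SDs
(`outlier_scale`), signed along the row's latent deviation with a wide
(0.5–1.5×) magnitude jitter so corrupted rows form a radial continuum
rather than a clump. Under `latent_correlation=0` the fallback construction
is continuous shifts plus random categorical flips. The detection pipeline
defines *flagging*; this construction defines what an outlier *is* for
evaluation purposes.

## Preprocessing

Order is fixed: special-code recoding → row-missingness filter → typed
imputation → standardization → outlier removal → balancing. Conventions:

- The missing-share denominator is the schema (predictor) columns only, and
  the > 20% inequality is strict.
- Imputation: continuous → mean, ordinal/nominal → mode, binary → least
  frequent observed category (a 50/50 tie imputes 0, a fixed deterministic
  rule). Imputation never invents unseen levels.
- Standardization for the unsupervised stage uses a fully numeric design
  that keeps continuous variables continuous (no epidemiological binning) —
  binning age/BMI here would erase exactly the extremeness the outlier
  stage must see. Zero-variance columns pass through as zeros.
- Outlier pipeline: the cluster count is selected *before* embedding — Ward
  linkage on the standardized matrix is cut at each k in 2–10 and scored by
  silhouette (ties → smallest k). The matrix is then projected to 2-D
  (t-SNE, perplexity 40, 5,000 iterations by default; PCA available for
  small deterministic fixtures), the embedding is Ward-clustered at the
  selected k, and rows beyond the 95th percentile of Euclidean distance to
  their cluster centroid are flagged (per cluster by default; a global-
  percentile variant is available). Outlier detection runs jointly over
  both cohorts by default (`joint_outliers=False` for per-cohort).
- Balancing is random down-sampling of the healthy group to the T2DM size,
  without replacement and unconditional on covariates; the direction is
  fixed and the reverse raises.

## Survival modeling

- Cox fits use Efron tie handling (ties are inevitable with year-scale
  times) and an L2 penalty, default 1e-2 (not empirically identified;
  exposed in config). Validation studies that compare against known truth
  use penalty 0 so confidence intervals are exact.
- Stepwise refinement operationalizes "no independent explanatory value":
  iteratively remove the largest-p term with p ≥ 0.05 provided the refit
  changes each remaining coefficient by < 10% relative (denominator floored
  at 0.1 on the log-hazard scale, so near-zero coefficients don't block
  removals) and costs < 2.0 partial log-likelihood units; refit after every
  removal so reported estimates always come from the final term set.
- Proportional hazards: per-term Schoenfeld-residual tests with the
  identity time transform. Flagged terms are refit in a time-varying Cox
  model on an episode-split (start, stop] dataset cut at a yearly grid,
  each flagged term carrying an x·t column evaluated at episode midpoints.
  The yearly grid is a deliberate resolution/size compromise (a split at
  every event time would be exact but enormous).
- Hazard table: β and HR print at two decimals; HR% derives from the
  *rounded* HR under the default `table` policy, matching the convention of
  published tables whose HR% column is internally consistent with the
  printed HR rather than with unrounded exp(β). An `exact` policy reports
  (exp(β) − 1)·100. `hr_percent(hr)` applies the printed-HR arithmetic
  directly.
- Risk scores are the linear predictor over the final model's base terms;
  covariate×time interaction terms never enter the score.
- Stratification: a Gini decision tree on score vs incidence, capped at
  five leaves, with every leaf holding ≥ 10% of participants
  (`min_leaf_fraction`). The floor exists because an unconstrained 5-leaf
  tree can carve tiny noise-pocket strata whose observed incidence breaks
  the risk gradient at moderate sample sizes; with it, stratum-wise
  incidence was monotone on every seed checked. Cross-validation re-derives
  the thresholds per fold and reports their SD; it never re-selects them.
  Printed ranges use two-decimal endpoints with 0.01 gaps; membership is
  half-open at the gap midpoints so every real score maps to exactly one
  stratum (a score equal to a cutpoint belongs to the upper stratum).
  Out-of-span scores clamp to the end strata with a warning.
- KM validation: product-limit curves per stratum, all pairwise log-rank
  χ²/p, and 25/50/75% survival percentiles with an infinity sentinel when a
  curve never crosses the threshold.

## Influence modeling

- Per-target networks are two-hidden-layer (64, 32) ReLU MLPs trained with
  an adaptive-moment optimizer; output heads follow the target scale
  (logistic for binary, linear for continuous, softmax for grouped
  categorical targets). Training hyperparameters are not externally
  specified anywhere authoritative, so defaults are conventional for small
  tabular networks: ≤ 200 epochs with early stopping on a held-out
  validation split (patience 20), batch 64, learning rate 1e-3, L2 1e-4.
  One known deviation: the implementation's L2 penalty applies to all
  weight matrices, not only the second hidden layer; the effective-weight
  statistic itself is unchanged.
- ANN encodings: continuous → min–max [0, 1]; smoking history → binary
  ever/never; six-level meat frequencies → binary top-band (the two highest
  frequency levels vs all lower); bread/cereal → full one-hot. Outcome and
  time columns are excluded before training.
- Ensembles: `runs` independent shuffles × `folds` CV folds per target
  (10 × 5 = 50 members at full scale); member seeds derive deterministically
  from (seed, run, fold). Members with single-class training splits are
  skipped; non-finite members are re-initialized once, then skipped.
- Effective weights are the ordered product of the three weight matrices
  (biases excluded), verified against brute-force path enumeration.
- Aggregation: median over all ensemble members; sign stability over all
  members (a per-fold variant would change little at these ensemble sizes).
  Exactly-zero effective weights count toward the smaller sign class
  (conservative); ties split as evenly as possible. "Unstable" is a split
  within 2 percentage points of 50/50; otherwise ≥ 70% is highly stable,
  60–69% moderately stable, < 60% low stability.
- Node granularity: by default every encoded feature is a network node
  (level-specific nodes for one-hot variables, which is how dietary types
  are reported); `grouped_targets=True` instead predicts one-hot blocks
  jointly through a softmax head, reducing per-class effective weights by
  the signed value of largest magnitude (`sum` optional). Influence
  matrices are reported raw (scale comparability across targets is limited;
  standardize per target downstream if needed).
- The difference matrix is elementwise disease-state minus healthy medians,
  with absolute values and opposite-sign reversal flags; it is antisymmetric
  under cohort swap by construction.

## Cohesion networks

- Edges: input → target where the median influence is strictly positive
  (threshold 0 by default; a magnitude threshold and a minimum-stability
  tier gate are available). Edge weight is the median magnitude.
- Centralities: degrees normalized by (n − 1); eigenvector centrality on
  in-edges (prestige convention — central means pointed at by influential
  nodes), scaled to max 1, with an undirected fallback on non-convergence;
  betweenness on shortest paths with distance = 1/weight (stronger
  influence = shorter path; unweighted variant available); PageRank with
  damping 0.85 (sums to 1). Deltas are disease-state minus healthy,
  reported at two decimals; vector shifts are arrows in a chosen 2-metric
  plane with Euclidean magnitudes and a behavioral-domain theme map
  (editable, `pipeline.DEFAULT_THEME_MAP`).
- Role classification (thresholds configurable): *dual-priority* = HR > 1,
  p < 0.05, and eigenvector or betweenness rises; *structural stabilizer* =
  HR < 1, p < 0.05, eigenvector falls; *emergent driver* = HR > 1,
  out-degree or betweenness rises while eigenvector does not; otherwise
  *other*. Categorical hazard terms map to their parent node; for nodes
  with several mapped terms the most significant term's HR is used.

## Validation studies and problem sizes

The studies in `behavnet.evaluation` (run by `tests/test_acceptance.py` and
`scripts/acceptance.py`) use these sizes, chosen so the full battery runs
in a few minutes on one CPU:

- Coefficient recovery: 20 replicates of a 25,000-row population (≈ 5,000
  events each) fitting all 32 reference terms without penalty; aggregate
  95% CI coverage across term × replicate events.
- Univariate screen calibration: 1,000 replicates of a 300-row cohort with
  one pure-noise binary term.
- Influence recovery: a 5-variable system (n = 2,000) with one noiseless
  planted dependence, default architecture, 2 runs × 3 folds.
- Outlier study: n = 2,000 with 5% contamination at 8 SD, full t-SNE
  pipeline.
- End-to-end demonstration: 600 participants per group, t-SNE at 1,000
  iterations, influence over an 8-node variable subset with 2 runs × 3
  folds.

## What the synthetic studies do and do not show

Passing these studies shows the machinery is internally correct and
statistically calibrated *under the generator's assumptions*: copula-
dependent covariates with exactly known marginals, a correctly specified
proportional-hazards event model, covariate-independent censoring, and
outliers that are genuine latent-space tail members. Real cohort data
differ in ways the generator does not emulate — informative censoring,
measurement error and reporting bias in self-reported behavior, non-
proportional effects beyond simple decay, missingness that is not at
random, and confounding structures richer than two latent factors. Results
on real data therefore inherit all the usual observational caveats, and
influence estimates in particular describe predictive co-occurrence, not
causal direction.

## Known limitations

- The unsupervised outlier stage has a structural recall ceiling when the
  flag rate (5% per cluster by the percentile definition) matches the
  contamination rate: recall then equals precision, demanding a
  near-perfect extremeness ranking from a 2-D embedding of predominantly
  categorical (hence saturating) data. In our studies recall is ~0.5–0.8
  under a PCA embedding and lower (~0.3–0.5) under t-SNE, whose adaptive
  bandwidth deliberately absorbs isolated points. The per-cluster 5% flag
  share itself always holds (it is the percentile definition). Treat the
  stage as data hygiene, not as a reliable anomaly detector.
- Effective weights are scale-dependent across targets with different
  output heads; compare within a target, or standardize per target before
  cross-target comparison.
- The stepwise rule, episode-split grid, stability band and role thresholds
  are reproducible operationalizations of qualitative descriptions; all are
  exposed as parameters.
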