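"""Cox risk model: screening, joint fit, hazard table, scores and strata.

Fits the laboratory-free behavioral Cox model on a simulated cohort,
prints a published-style hazard table (beta, exp(beta), HR%, CI), computes
two worked risk-score profiles against the reference coefficients, and
stratifies the cohort into five validated risk groups.
"""

import pandas as pd

from behavnet import (GeneratorConfig, default_schema, generate_cohort_pair,
                      PROFILE_HIGH_RISK, PROFILE_PROTECTIVE, REFERENCE_BETAS)
from behavnet.schema import cox_design
from behavnet import survival as surv

schema = default_schema()
config = GeneratorConfig(n_per_group=1500, seed=3)
healthy, t2dm = generate_cohort_pair(config, schema)
pooled = pd.concat([healthy.head(1500), t2dm], ignore_index=True)

design = cox_design(pooled, schema)
df = pd.concat([design, pooled[["follow_up_years", "event"]]], axis=1)

terms = surv.low_variance_filter(design, pooled["event"], 0.01)
terms = surv.vif_filter(design[terms], 10.0)
terms = surv.univariate_screen(df, terms, alpha=0.05)
print(f"{len(terms)} terms survive the univariate screen")

fit = surv.fit_multivariate_cox(df, terms, l2=1e-2)
ph_flags, fit = surv.test_proportional_hazards(fit, df)
print(f"final model: {len(fit.terms)} terms; "
      f"PH violations: {ph_flags['flagged'] or 'none'}")

table = surv.hazard_table(fit)
print("\nhazard table (head):")
print(table.head(6).to_string(index=False))

# Worked profiles against the reference coefficient set:
lo = surv.risk_score(REFERENCE_BETAS, PROFILE_PROTECTIVE)
hi = surv.risk_score(REFERENCE_BETAS, PROFILE_HIGH_RISK)
print(f"\nworked risk scores: protective profile {lo:.2f}, "
      f"high-risk profile {hi:.2f}")

scores = surv.risk_scores(fit.base_betas, design)
strat = surv.derive_strata(scores, pooled["event"], seed=0)
labels = surv.assign_stratum(scores.to_numpy(), strat)
print("\nstratum score ranges and observed incidence:")
inc = pooled.groupby(labels)["event"].mean()
for lab in strat.labels:
    lo_r, hi_r = strat.ranges[lab]
    print(f"  {lab:<10} [{lo_r:6.2f}, {hi_r:6.2f}]  incidence "
          f"{inc.get(lab, float('nan')):.2f}")

km = surv.km_validation(pooled, labels)
worst = min(t["p"] for t in km.pairwise_tests)
print(f"\npairwise log-rank: {len(km.pairwise_tests)} tests, "
      f"smallest p = {worst:.2e}")
# A rising incidence from very_low to very_high with separated KM curves
# shows the linear predictor orders participants by real event risk.
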