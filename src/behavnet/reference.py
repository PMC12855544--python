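"""Reference hazard coefficients for the default behavioral risk model.

The log-hazard coefficients below are the published multivariate Cox
estimates for the laboratory-free behavioral T2DM model that the default
schema mirrors.  They serve two purposes:

* as the default ``betas`` of the synthetic-cohort generator, so that
  simulated event times carry a realistic effect structure, and
* as the coefficient set for worked risk-score examples (the linear
  predictor of the final model, :func:`behavnet.survival.risk_score`).

Keys are Cox design column names produced by :func:`behavnet.schema.cox_design`.
Dummy levels without a published coefficient (the rare ``daily`` meat levels)
default to 0.0.
"""

from __future__ import annotations

REFERENCE_BETAS: dict[str, float] = {
    "loneliness_isolation": 0.13,
    "seen_psychiatrist": 0.16,
    "sleeplessness_insomnia": 0.06,
    "fed_up_feelings": 0.08,
    "tense_highly_strung": 0.15,
    "sleep_duration_7_8h": -0.13,
    "nap_during_day": 0.09,
    "difficulty_getting_up": 0.04,
    "plays_computer_games": 0.04,
    "smoking_status[previous]": 0.12,
    "smoking_status[current]": 0.17,
    "current_tobacco_smoking": 0.29,
    "salt_added_to_food": 0.04,          # per ordinal step
    "cheese_intake": -0.05,
    "bread_type[brown]": 0.16,
    "bread_type[white]": 0.26,
    "bread_type[other]": 0.11,
    "processed_meat_intake[lt_once_week]": 0.07,
    "processed_meat_intake[once_week]": 0.05,
    "processed_meat_intake[2_4_week]": 0.06,
    "processed_meat_intake[5_6_week]": 0.17,
    "beef_intake[5_6_week]": 0.16,
    "cereal_type[biscuit]": 0.10,
    "cereal_type[oat]": -0.23,
    "cereal_type[muesli]": -0.55,
    "cereal_type[sugary]": 0.10,
    "age[50_59]": -0.06,
    "age[60_70]": 0.42,
    "bmi[25_29.9]": -0.71,
    "bmi[30_34.9]": 0.08,
    "bmi[35_39.9]": 0.43,
    "bmi[40_50]": 0.58,
}

# Published risk-stratum score ranges for the five-leaf stratification of the
# reference model's linear predictor (two-decimal printed endpoints).
REFERENCE_STRATA_RANGES: dict[str, tuple[float, float]] = {
    "very_low": (-1.67, 0.22),
    "low": (0.23, 0.40),
    "moderate": (0.41, 0.70),
    "high": (0.71, 1.11),
    "very_high": (1.12, 2.75),
}

# Published paired influence coefficients (healthy, disease-state) for
# selected directed variable pairs, with the published difference.  Used as
# arithmetic anchors for the difference-matrix computation.
REFERENCE_INFLUENCE_PAIRS: list[dict] = [
    {"input": "white_bread", "target": "sleeplessness_insomnia",
     "healthy": -1.28, "t2dm": 0.23, "difference": 1.51},
    {"input": "beef_intake", "target": "seen_psychiatrist",
     "healthy": 1.43, "t2dm": -0.94, "difference": -2.37},
    {"input": "loneliness_isolation", "target": "sugary_cereal",
     "healthy": -1.07, "t2dm": 0.93, "difference": 2.00},
    {"input": "brown_bread", "target": "tense_highly_strung",
     "healthy": -0.97, "t2dm": 0.71, "difference": 1.68},
]

# Published per-node centrality values (healthy, disease-state) and their
# published shifts, for the delta-table arithmetic anchors.
REFERENCE_CENTRALITY: list[dict] = [
    {"node": "current_tobacco_smoking",
     "eigenvector": (0.43, 0.87, 0.44), "in_degree": (0.44, 0.72, 0.28),
     "out_degree": (0.28, 0.52, 0.24)},
    {"node": "muesli",
     "eigenvector": (0.07, 0.01, -0.07), "in_degree": (0.48, 0.20, -0.28),
     "out_degree": (0.60, 0.36, -0.24)},
    {"node": "age",
     "eigenvector": (0.24, 0.10, -0.14), "in_degree": (0.52, 0.36, -0.16),
     "out_degree": (0.48, 0.40, -0.08)},
    {"node": "bmi",
     "eigenvector": (0.47, 0.18, -0.29), "in_degree": (0.56, 0.56, 0.00),
     "out_degree": (0.44, 0.56, 0.12)},
]

# Worked example profiles: non-reference indicator settings only.
PROFILE_PROTECTIVE = {
    "loneliness_isolation": 1.0,
    "sleep_duration_7_8h": 1.0,
    "cereal_type[muesli]": 1.0,
}  # linear predictor 0.13 - 0.13 - 0.55 = -0.55 -> very_low

PROFILE_HIGH_RISK = {
    "loneliness_isolation": 1.0,
    "nap_during_day": 1.0,
    "smoking_status[current]": 1.0,
    "cereal_type[sugary]": 1.0,
    "age[60_70]": 1.0,
}  # linear predictor 0.13 + 0.09 + 0.17 + 0.10 + 0.42 = 0.91 -> high
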