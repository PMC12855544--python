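"""Directed cohesion networks, centrality shifts and role classification.

Builds two influence networks from paired (healthy vs disease-state)
reference influence coefficients, computes five centralities per node,
their healthy -> T2DM shifts and vector-shift arrows, and combines the
shifts with hazard ratios into intervention-relevance roles.
"""

import pandas as pd

from behavnet.influence import InfluenceEstimate, InfluenceMatrix
from behavnet.network import (build_network, centrality_deltas,
                              centrality_profile, classify_roles,
                              vector_shift)

# Paired directed influences for a small illustrative variable set.
PAIRS = {
    ("current_tobacco_smoking", "fed_up_feelings"): (0.20, 0.90),
    ("current_tobacco_smoking", "sleeplessness_insomnia"): (0.10, 0.80),
    ("loneliness_isolation", "current_tobacco_smoking"): (-0.20, 0.60),
    ("muesli", "fed_up_feelings"): (0.60, 0.05),
    ("muesli", "loneliness_isolation"): (0.50, -0.10),
    ("fed_up_feelings", "muesli"): (0.30, -0.20),
    ("sleeplessness_insomnia", "fed_up_feelings"): (0.40, 0.50),
    ("loneliness_isolation", "sleeplessness_insomnia"): (0.10, 0.55),
}


def matrix(which, label):
    ests = {k: InfluenceEstimate(input=k[0], target=k[1],
                                 median_weight=v[which], pct_positive=85,
                                 pct_negative=15, tier="highly_stable")
            for k, v in PAIRS.items()}
    nodes = sorted({k[0] for k in PAIRS} | {k[1] for k in PAIRS})
    return InfluenceMatrix(variables=nodes, estimates=ests, cohort_label=label)


healthy_g = build_network(matrix(0, "healthy"))
t2dm_g = build_network(matrix(1, "t2dm"))
prof_h = centrality_profile(healthy_g, "healthy")
prof_t = centrality_profile(t2dm_g, "t2dm")

deltas = centrality_deltas(prof_h, prof_t)
print("centrality shifts (healthy -> T2DM):")
print(deltas[["delta_in_degree", "delta_out_degree",
              "delta_eigenvector"]].to_string())

arrows = vector_shift(prof_h, prof_t)
print("\nvector-shift magnitudes:")
print(arrows["magnitude"].round(3).to_string())

hazards = pd.DataFrame({
    "term": ["current_tobacco_smoking", "muesli", "loneliness_isolation",
             "sleeplessness_insomnia", "fed_up_feelings"],
    "hr": [1.34, 0.57, 1.14, 1.06, 1.08],
    "p": [1e-4, 1e-4, 1e-4, 0.02, 1e-3],
})
roles = classify_roles(deltas, hazards)
print("\nrole classification:")
print(roles[["category", "hr"]].to_string())
# Nodes that are risky AND gain centrality are dual-priority targets;
# protective nodes that lose centrality are eroding structural stabilizers.
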