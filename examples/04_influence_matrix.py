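"""ANN effective-weight influence matrix on a planted toy system.

Builds a 5-variable system with one noiseless dependence (x -> y), trains a
small feedforward ensemble per target, extracts path-product effective
weights, and shows that the planted pair dominates the influence matrix
with a stable sign across ensemble members.
"""

import numpy as np
import pandas as pd

from behavnet import NetworkArchitecture, VariableSpec, build_influence_matrix

rng = np.random.default_rng(0)
n = 800
x = rng.uniform(size=n)
table = pd.DataFrame({
    "x": x,
    "y": (x > 0.5).astype(int),          # deterministic function of x
    "v0": rng.integers(0, 2, n),
    "v1": rng.integers(0, 2, n),
    "v2": rng.integers(0, 2, n),
})
schema = [VariableSpec(name="x", scale="continuous",
                       cox_encoding="ordinal_numeric",
                       ann_encoding="minmax_continuous",
                       gen_params={"range": [0, 1]})]
schema += [VariableSpec(name=v, scale="binary", levels=[0, 1],
                        reference_level=0, gen_params={"probs": [0.5, 0.5]})
           for v in ("y", "v0", "v1", "v2")]

arch = NetworkArchitecture(hidden_sizes=(16, 8), epochs=100)
matrix = build_influence_matrix(table, schema, arch, runs=2, folds=3, seed=1,
                                cohort_label="toy")

frame = matrix.to_frame()
frame["abs"] = frame["median_weight"].abs()
print("top influences by |median effective weight|:")
print(frame.nlargest(5, "abs")[["input", "target", "median_weight",
                                "pct_positive", "tier"]].to_string(index=False))
# The planted x -> y edge should top the table with pct_positive near 100
# (highly stable); everything else is noise near zero with unstable signs.
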