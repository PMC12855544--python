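"""End-to-end pipeline run: simulate -> preprocess -> survival -> influence
-> network -> report, from a single serializable configuration.

Uses a small problem size so the run finishes in well under a minute;
every artifact (hazard table, strata, KM curves, influence matrices,
difference matrix, centrality deltas, roles, markdown report) lands in the
run directory together with a manifest of row counts and checksums.
"""

import json
from pathlib import Path

from behavnet import PipelineConfig, run_pipeline

out = Path("scratch/example_run")
config = PipelineConfig(
    out_dir=str(out), seed=11,
    simulate={"n_per_group": 250, "missing_row_fraction": 0.05,
              "missing_cell_rate": 0.02, "outlier_fraction": 0.02},
    preprocess={"outlier_method": "pca"},
    influence={"runs": 1, "folds": 2, "hidden_sizes": (16, 8), "epochs": 60,
               "variables": ["loneliness_isolation", "sleeplessness_insomnia",
                             "fed_up_feelings", "current_tobacco_smoking",
                             "cereal_type=muesli", "bread_type=white"]},
    include_plots=False,
)
run_dir = run_pipeline(config)

manifest = json.loads((run_dir / "manifest.json").read_text())
print(f"pipeline finished; last good stage: {manifest['last_good_stage']}")
for stage, info in manifest["stages"].items():
    print(f"  {stage:<10} rows={info['rows']}")
print(f"\nreport: {run_dir / 'report.md'}")
print("artifacts:", ", ".join(sorted(
    f for s in manifest["stages"].values() for f in s["artifacts"])))
# Re-running with the same config reproduces byte-identical artifacts; the
# manifest checksums make that verifiable.
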