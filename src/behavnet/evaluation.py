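"""Validation studies: calibration, recovery and consistency checks.

Each function here runs one self-contained study against the package's own
machinery — arithmetic consistency of the published-style tables, oracle
equivalence of the effective-weight computation, statistical calibration of
the screening and fitting stages on synthetic cohorts with known truth,
recovery of planted influence signals, and end-to-end pipeline behavior.
They are used by the test suite and by ``scripts/acceptance.py``.

All randomness is controlled through an explicit seed; problem sizes are
chosen so the full battery completes on a single CPU in minutes.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from . import schema as sch
from . import simulate as sim
from . import survival as surv
from .influence import (InfluenceEstimate, InfluenceMatrix,
                        NetworkArchitecture, aggregate_influence,
                        build_influence_matrix, difference_matrix,
                        effective_weights)
from .network import centrality_deltas, centrality_profile
from .preprocess import detect_outliers, standardize
from .reference import (PROFILE_HIGH_RISK, PROFILE_PROTECTIVE,
                        REFERENCE_BETAS, REFERENCE_CENTRALITY,
                        REFERENCE_INFLUENCE_PAIRS)
from .schema import VariableSpec
from .survival import hr_percent, risk_score

__all__ = [
    "worked_risk_scores", "hazard_table_arithmetic",
    "difference_matrix_arithmetic", "centrality_delta_arithmetic",
    "effective_weight_oracle", "stability_tier_checks", "cox_beta_coverage",
    "univariate_null_calibration", "influence_signal_recovery",
    "outlier_detection_study", "network_property_checks", "cindex_checks",
    "smoke_run",
]


# ----------------------------------------------------------------------
# arithmetic anchors (instantaneous)
# ----------------------------------------------------------------------

def worked_risk_scores() -> dict:
    """Linear-predictor scores of the two worked example profiles."""
    return {
        "protective": risk_score(REFERENCE_BETAS, PROFILE_PROTECTIVE),
        "high_risk": risk_score(REFERENCE_BETAS, PROFILE_HIGH_RISK),
    }


def hazard_table_arithmetic() -> dict:
    """beta -> HR -> HR% arithmetic under the table-matching policy."""
    from .survival import CoxFitResult
    rows = [
        {"name": "current_tobacco_smoking", "beta": 0.29},
        {"name": "loneliness_isolation", "beta": 0.13},
        {"name": "fed_up_feelings", "beta": 0.08},
        {"name": "cereal_type[oat]", "beta": -0.23},
    ]
    fit = CoxFitResult(terms=[{**r, "se": 0.0, "hr": np.exp(r["beta"]),
                               "hr_pct": 0.0, "p": 0.0, "ci_low": 1.0,
                               "ci_high": 1.0} for r in rows])
    tab = surv.hazard_table(fit).set_index("term")
    return {
        "hr_tobacco": float(tab.loc["current_tobacco_smoking", "hr"]),
        "hr_pct_tobacco": float(tab.loc["current_tobacco_smoking", "hr_pct"]),
        "hr_loneliness": float(tab.loc["loneliness_isolation", "hr"]),
        "hr_pct_fed_up": float(tab.loc["fed_up_feelings", "hr_pct"]),
        "hr_pct_oat": float(tab.loc["cereal_type[oat]", "hr_pct"]),
        "hr_pct_from_printed_hr_muesli": hr_percent(0.57),
    }


def _matrix_from_pairs(values, label) -> InfluenceMatrix:
    ests = {(p["input"], p["target"]): InfluenceEstimate(
        input=p["input"], target=p["target"], median_weight=p[label],
        pct_positive=50.0, pct_negative=50.0, tier="unstable")
        for p in values}
    variables = sorted({p["input"] for p in values}
                       | {p["target"] for p in values})
    return InfluenceMatrix(variables=variables, estimates=ests,
                           cohort_label=label)


def difference_matrix_arithmetic() -> dict:
    """Disease-minus-healthy differences on the reference influence pairs."""
    healthy = _matrix_from_pairs(REFERENCE_INFLUENCE_PAIRS, "healthy")
    t2dm = _matrix_from_pairs(REFERENCE_INFLUENCE_PAIRS, "t2dm")
    diff = difference_matrix(t2dm, healthy).set_index(["input", "target"])
    out = {}
    for p in REFERENCE_INFLUENCE_PAIRS:
        row = diff.loc[(p["input"], p["target"])]
        key = f"{p['input']}__{p['target']}"
        out[f"diff_{key}"] = round(float(row["difference"]), 2)
        out[f"reversal_{key}"] = bool(row["sign_reversal"])
    return out


def centrality_delta_arithmetic() -> dict:
    """Healthy -> disease-state centrality shifts on the reference profiles."""
    metrics = ["in_degree", "out_degree", "eigenvector"]
    idx = [r["node"] for r in REFERENCE_CENTRALITY]
    healthy = pd.DataFrame(
        {m: [r[m][0] for r in REFERENCE_CENTRALITY] for m in metrics}
        | {"betweenness": 0.0, "pagerank": 0.0}, index=idx)
    t2dm = pd.DataFrame(
        {m: [r[m][1] for r in REFERENCE_CENTRALITY] for m in metrics}
        | {"betweenness": 0.0, "pagerank": 0.0}, index=idx)
    d = centrality_deltas(healthy, t2dm)
    out = {}
    for r in REFERENCE_CENTRALITY:
        for m in metrics:
            out[f"delta_{m}_{r['node']}"] = float(d.loc[r["node"], f"delta_{m}"])
    return out


# ----------------------------------------------------------------------
# oracle equivalence and tier classification (fast)
# ----------------------------------------------------------------------

def effective_weight_oracle(seed: int = 0, draws: int = 20) -> dict:
    """Path-product vs brute-force triple-loop enumeration on small nets."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(draws):
        d, h1, h2, k = 6, 4, 3, 2
        W = (rng.standard_normal((d, h1)), rng.standard_normal((h1, h2)),
             rng.standard_normal((h2, k)))
        eff = effective_weights(W)
        brute = np.zeros((d, k))
        for i in range(d):
            for o in range(k):
                for a in range(h1):
                    for b in range(h2):
                        brute[i, o] += W[0][i, a] * W[1][a, b] * W[2][b, o]
        worst = max(worst, float(np.abs(eff - brute).max()))
    return {"max_abs_deviation": worst, "draws": draws}


def stability_tier_checks() -> dict:
    """Sign-split fixtures against their expected stability tiers."""
    cases = [
        (45, 5, "highly_stable"), (32, 18, "moderately_stable"),
        (11, 9, "low_stability"), (25, 25, "unstable"),
    ]
    agree = 0
    for pos, neg, expected in cases:
        samples = np.r_[np.ones(pos), -np.ones(neg)]
        if aggregate_influence(samples).tier == expected:
            agree += 1
    return {"agreement": agree, "cases": len(cases)}


# ----------------------------------------------------------------------
# statistical calibration on synthetic cohorts (minutes)
# ----------------------------------------------------------------------

def cox_beta_coverage(seed: int = 0, replicates: int = 20,
                      n_population: int = 25_000) -> dict:
    """95% CI coverage of the true coefficients over seeded replicates.

    Each replicate simulates a fresh population (about 5,000 events and
    the rest censored at the default event rate), fits the full reference
    term set jointly (no penalty, no stepwise) and records, for every term,
    whether the true coefficient falls inside its 95% CI.  Reports the
    aggregate coverage over term x replicate events.
    """
    schema = sch.default_schema()
    covered = total = 0
    for r in range(replicates):
        rep_seed = (seed * 7919 + r * 104_729) % (2**31 - 1)
        cov = sim.simulate_covariates(schema, n_population, seed=rep_seed,
                                      latent_correlation=0.8)
        cfg = sim.GeneratorConfig(seed=rep_seed)
        data = sim.simulate_survival(cov, cfg, schema,
                                     seed=rep_seed + 1)
        design = sch.cox_design(data, schema)
        df = pd.concat([design, data[[surv.DURATION, surv.EVENT]]], axis=1)
        fit = surv.fit_multivariate_cox(df, list(REFERENCE_BETAS), l2=0.0,
                                        stepwise=False)
        for t in fit.terms:
            lo, hi = np.log(t["ci_low"]), np.log(t["ci_high"])
            covered += int(lo <= REFERENCE_BETAS[t["name"]] <= hi)
            total += 1
    return {"coverage": covered / total, "replicates": replicates,
            "terms": total // replicates}


def univariate_null_calibration(seed: int = 0, replicates: int = 1000,
                                n: int = 300) -> dict:
    """Type-I error of the univariate screen on a pure-noise term."""
    rng = np.random.default_rng(seed)
    retained = 0
    for r in range(replicates):
        x = rng.integers(0, 2, n).astype(float)
        T = rng.exponential(10.0, n)
        df = pd.DataFrame({"noise": x,
                           surv.DURATION: np.minimum(T, 15.0),
                           surv.EVENT: (T <= 15.0).astype(int)})
        if surv.univariate_screen(df, ["noise"], alpha=0.05):
            retained += 1
    return {"retention_rate": retained / replicates,
            "replicates": replicates}


def influence_signal_recovery(seed: int = 0, n: int = 2000) -> dict:
    """Planted noiseless linear dependence in a 5-variable system.

    Trains the default architecture with 2 runs x 3 folds per target and
    checks that the planted x -> y pair carries the top-magnitude median
    effective weight with stable sign.
    """
    rng = np.random.default_rng(seed)
    x = rng.uniform(size=n)
    df = pd.DataFrame({
        "x": x, "y": (x > 0.5).astype(int),
        "v0": rng.integers(0, 2, n), "v1": rng.integers(0, 2, n),
        "v2": rng.integers(0, 2, n),
    })
    toy = [VariableSpec(name="x", scale="continuous",
                        cox_encoding="ordinal_numeric",
                        ann_encoding="minmax_continuous",
                        gen_params={"range": [0, 1]})]
    for v in ("y", "v0", "v1", "v2"):
        toy.append(VariableSpec(name=v, scale="binary", levels=[0, 1],
                                reference_level=0,
                                gen_params={"probs": [0.5, 0.5]}))
    mat = build_influence_matrix(df, toy, NetworkArchitecture(), runs=2,
                                 folds=3, seed=seed, cohort_label="toy")
    frame = mat.to_frame()
    top = frame.loc[frame["median_weight"].abs().idxmax()]
    planted = mat.estimates[("x", "y")]
    return {
        "top_pair_is_planted": float((top["input"], top["target"]) == ("x", "y")),
        "planted_pct_stable_sign": float(max(planted.pct_positive,
                                             planted.pct_negative)),
        "n": n,
    }


def outlier_detection_study(seed: int = 0, n_total: int = 2000,
                            contamination: float = 0.05,
                            method: str = "tsne", n_iter: int = 5000) -> dict:
    """Recall of injected ground-truth outliers by the unsupervised pipeline.

    Generates a two-group cohort of ``n_total`` rows, corrupts a
    ``contamination`` share into 8-SD ground-truth outliers, runs the full
    standardize -> embed -> silhouette/Ward -> per-cluster 95th percentile
    pipeline, and reports recall plus the largest per-cluster deviation of
    the flagged count from 5% of cluster size (in rows).
    """
    schema = sch.default_schema()
    cfg = sim.GeneratorConfig(n_per_group=n_total // 2, healthy_surplus=0.0,
                              outlier_fraction=contamination,
                              outlier_scale=8.0, seed=seed)
    healthy, t2dm = sim.generate_cohort_pair(cfg, schema)
    pool = pd.concat([healthy, t2dm], ignore_index=True)
    pool, truth = sim.inject_outliers(pool, schema, cfg)
    z = standardize(pool, schema)
    rep = detect_outliers(z, method=method, n_iter=n_iter, seed=seed)
    flagged = set(rep.flagged_rows.tolist())
    recall = len(flagged & set(truth.tolist())) / max(len(truth), 1)
    worst_share_dev = 0.0
    for c in np.unique(rep.cluster_labels):
        m = rep.cluster_labels == c
        n_flag = int(np.isin(np.flatnonzero(m), rep.flagged_rows).sum())
        worst_share_dev = max(worst_share_dev,
                              abs(n_flag - 0.05 * int(m.sum())))
    return {"recall": recall, "k_selected": int(rep.k_selected),
            "worst_flag_share_deviation_rows": worst_share_dev,
            "n": len(pool)}


def network_property_checks(seed: int = 0) -> dict:
    """Centrality normalization invariants + brute-force betweenness oracle."""
    import networkx as nx
    rng = np.random.default_rng(seed)
    worst_pr = worst_btw = 0.0
    for g_seed in range(5):
        g = nx.DiGraph()
        n = 6
        g.add_nodes_from(range(n))
        grng = np.random.default_rng(seed * 100 + g_seed)
        for u, v in itertools.permutations(range(n), 2):
            if grng.uniform() < 0.3:
                g.add_edge(u, v, weight=1.0, distance=1.0)
        if g.number_of_edges() == 0:
            continue
        prof = centrality_profile(g, weighted_paths=False)
        worst_pr = max(worst_pr, abs(prof["pagerank"].sum() - 1.0))
        assert prof["in_degree"].between(0, 1).all()
        assert prof["out_degree"].between(0, 1).all()
        brute = {v: 0.0 for v in g}
        for s, t in itertools.permutations(g.nodes, 2):
            try:
                paths = list(nx.all_shortest_paths(g, s, t))
            except nx.NetworkXNoPath:
                continue
            for v in g:
                if v not in (s, t):
                    brute[v] += sum(1 for p in paths if v in p[1:-1]) / len(paths)
        scale = 1.0 / ((n - 1) * (n - 2))
        for v in g:
            worst_btw = max(worst_btw,
                            abs(prof.loc[v, "betweenness"] - brute[v] * scale))
    return {"pagerank_sum_max_deviation": worst_pr,
            "betweenness_oracle_max_deviation": worst_btw}


def cindex_checks(seed: int = 0, n: int = 2000) -> dict:
    """Concordance boundary behavior: strong signal vs pure noise."""
    rng = np.random.default_rng(seed)
    out = {}
    for name, beta in (("strong", 30.0), ("noise", 0.0)):
        x = rng.uniform(size=n)
        T = rng.exponential(10.0, n) * np.exp(-beta * x)
        df = pd.DataFrame({"x": x, surv.DURATION: T, surv.EVENT: 1})
        cv = surv.cross_validate_cindex(df, ["x"], l2=0.0, folds=5, seed=seed)
        out[f"cindex_{name}"] = cv["mean"]
    return out


def smoke_run(seed: int, out_dir, n_per_group: int = 600) -> dict:
    """Demonstration pipeline run; checks stratum-wise incidence ordering."""
    from .pipeline import PipelineConfig, run_pipeline
    cfg = PipelineConfig(
        out_dir=str(out_dir), seed=seed,
        simulate={"n_per_group": n_per_group, "missing_row_fraction": 0.05,
                  "missing_cell_rate": 0.02, "outlier_fraction": 0.02},
        preprocess={"outlier_method": "tsne", "n_iter": 1000},
        influence={"runs": 2, "folds": 3,
                   "variables": ["loneliness_isolation", "fed_up_feelings",
                                 "sleeplessness_insomnia",
                                 "current_tobacco_smoking",
                                 "cereal_type=muesli", "bread_type=white",
                                 "age", "bmi"]},
        include_plots=False,
    )
    run_dir = run_pipeline(cfg)
    scored = pd.read_csv(run_dir / "risk_scores.csv")
    order = ["very_low", "low", "moderate", "high", "very_high"]
    inc = scored.groupby("stratum")["event"].mean()
    series = [float(inc[s]) for s in order if s in inc.index]
    monotone = all(a < b for a, b in zip(series, series[1:]))
    import json
    manifest = json.loads((run_dir / "manifest.json").read_text())
    return {"incidence_by_stratum": series,
            "incidence_monotone": float(monotone),
            "completed": float(manifest["last_good_stage"] == "report"),
            "n_per_group": n_per_group}
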