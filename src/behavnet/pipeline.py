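"""End-to-end pipeline: simulate -> preprocess -> survival -> influence -> network -> report.

Each stage consumes only files written by earlier stages (never in-memory
state), so any stage can be re-run from prior artifacts.  A manifest records
the config hash, per-stage row counts, seeds and output checksums; fixed
config implies byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import influence as infl
from . import network as net
from . import preprocess as prep
from . import schema as sch
from . import simulate as sim
from . import survival as surv

__all__ = ["PipelineConfig", "run_pipeline", "render_report",
           "influence_from_frame", "DEFAULT_THEME_MAP"]

STAGES = ("simulate", "preprocess", "survival", "influence", "network", "report")

#: behavioral-domain themes for vector-shift coloring (editable)
DEFAULT_THEME_MAP = {
    "loneliness_isolation": "psychological", "seen_psychiatrist": "psychological",
    "fed_up_feelings": "psychological", "tense_highly_strung": "psychological",
    "sleeplessness_insomnia": "sleep", "sleep_duration_7_8h": "sleep",
    "nap_during_day": "sleep", "difficulty_getting_up": "sleep",
    "plays_computer_games": "lifestyle", "smoking_status": "lifestyle",
    "current_tobacco_smoking": "lifestyle",
    "salt_added_to_food": "dietary", "cheese_intake": "dietary",
    "processed_meat_intake": "dietary", "beef_intake": "dietary",
    "age": "demographic", "bmi": "demographic",
}


class SimulateParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_per_group: int = 600
    baseline_shape: float = 1.2
    baseline_scale: float = 50.0
    max_follow: float = 17.0
    missing_row_fraction: float = 0.05
    missing_cell_rate: float = 0.02
    outlier_fraction: float = 0.02
    outlier_scale: float = 8.0


class PreprocessParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    missing_threshold: float = 0.20
    outlier_method: str = "tsne"
    perplexity: float = 40.0
    n_iter: int = 1000
    joint_outliers: bool = True


class SurvivalParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    l2: float = 1e-2
    alpha: float = 0.05
    vif_threshold: float = 10.0
    min_level_freq: float = 0.01
    cv_folds: int = 10
    n_leaves: int = 5


class InfluenceParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    runs: int = 2
    folds: int = 3
    hidden_sizes: tuple[int, int] = (64, 32)
    epochs: int = 200
    l2: float = 1e-4
    variables: Optional[list[str]] = None   # node subset; None = all features


class NetworkParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    edge_threshold: float = 0.0
    min_tier: Optional[str] = None


class PipelineConfig(BaseModel):
    """Fully serializable pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    out_dir: str
    seed: int = 0
    simulate: SimulateParams = SimulateParams()
    preprocess: PreprocessParams = PreprocessParams()
    survival: SurvivalParams = SurvivalParams()
    influence: InfluenceParams = InfluenceParams()
    network: NetworkParams = NetworkParams()
    include_plots: bool = True

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, index=False):
    df.to_csv(path, index=index, float_format="%.10g")


def influence_from_frame(df: pd.DataFrame) -> infl.InfluenceMatrix:
    """Rebuild an InfluenceMatrix from its long-format CSV frame."""
    estimates = {}
    for _, r in df.iterrows():
        estimates[(r["input"], r["target"])] = infl.InfluenceEstimate(
            input=r["input"], target=r["target"],
            median_weight=float(r["median_weight"]),
            pct_positive=float(r["pct_positive"]),
            pct_negative=float(r["pct_negative"]), tier=r["tier"])
    variables = sorted(set(df["input"]) | set(df["target"]))
    label = df["cohort"].iloc[0] if "cohort" in df and len(df) else ""
    return infl.InfluenceMatrix(variables=variables, estimates=estimates,
                                cohort_label=label)


# ----------------------------------------------------------------------
def run_pipeline(config: PipelineConfig, stages: tuple = STAGES) -> Path:
    """Execute the pipeline stages in order, writing artifacts + manifest.

    Returns the run directory.  A stage failure aborts with the manifest
    marking the last good stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_json = config.model_dump_json(indent=2)
    (out / "config.json").write_text(cfg_json)
    manifest = {
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed, "stages": {}, "last_good_stage": None,
    }
    schema = sch.default_schema()
    (out / "schema.json").write_text(json.dumps(sch.schema_to_json(schema),
                                                indent=2, default=str))
    try:
        for stage in STAGES:
            if stage not in stages:
                continue
            info = _STAGE_FN[stage](config, schema, out)
            artifacts = {}
            for f in sorted(info.get("artifacts", [])):
                artifacts[f] = _sha256(out / f)
            manifest["stages"][stage] = {
                "rows": info.get("rows", {}), "artifacts": artifacts,
            }
            manifest["last_good_stage"] = stage
    finally:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _stage_simulate(config: PipelineConfig, schema, out: Path) -> dict:
    p = config.simulate
    gc = sim.GeneratorConfig(
        n_per_group=p.n_per_group, baseline_shape=p.baseline_shape,
        baseline_scale=p.baseline_scale, max_follow=p.max_follow,
        missing_row_fraction=p.missing_row_fraction,
        missing_cell_rate=p.missing_cell_rate,
        outlier_fraction=p.outlier_fraction, outlier_scale=p.outlier_scale,
        seed=config.seed)
    healthy, t2dm = sim.generate_cohort_pair(gc, schema)
    files = []
    for name, df in (("healthy", healthy), ("t2dm", t2dm)):
        df = sim.inject_missingness(df, schema, gc,
                                    seed=config.seed + (1 if name == "healthy" else 2))
        df, idx = sim.inject_outliers(df, schema, gc,
                                      seed=config.seed + (3 if name == "healthy" else 4))
        f = f"cohort_{name}.csv"
        _write_csv(df, out / f)
        files.append(f)
        (out / f"outlier_truth_{name}.json").write_text(json.dumps(idx.tolist()))
        files.append(f"outlier_truth_{name}.json")
    return {"artifacts": files,
            "rows": {"healthy": len(healthy), "t2dm": len(t2dm)}}


def _read_cohort(path: Path, schema) -> pd.DataFrame:
    df = pd.read_csv(path)
    for spec in schema:   # keep categorical levels as objects, codes as ints
        if spec.name in df.columns and not spec.is_continuous:
            if spec.scale == "binary":
                continue
            df[spec.name] = df[spec.name].astype(object)
    return df


def _stage_preprocess(config: PipelineConfig, schema, out: Path) -> dict:
    p = config.preprocess
    healthy = _read_cohort(out / "cohort_healthy.csv", schema)
    t2dm = _read_cohort(out / "cohort_t2dm.csv", schema)
    code_map = {-1: "missing", -3: "missing"}
    res = prep.preprocess_cohorts(
        healthy, t2dm, schema, special_code_map=code_map,
        missing_threshold=p.missing_threshold,
        outlier_method=p.outlier_method, outlier_seed=config.seed,
        joint_outliers=p.joint_outliers, balance_seed=config.seed,
        perplexity=p.perplexity, n_iter=p.n_iter)
    files = []
    for name in ("healthy", "t2dm"):
        f = f"clean_{name}.csv"
        _write_csv(res[name], out / f)
        files.append(f)
    reports = {k: v.to_json() for k, v in res["outlier_reports"].items()}
    (out / "outlier_report.json").write_text(json.dumps(reports))
    files.append("outlier_report.json")
    return {"artifacts": files, "rows": res["log"]}


def _stage_survival(config: PipelineConfig, schema, out: Path) -> dict:
    p = config.survival
    healthy = _read_cohort(out / "clean_healthy.csv", schema)
    t2dm = _read_cohort(out / "clean_t2dm.csv", schema)
    pooled = pd.concat([healthy, t2dm], ignore_index=True)
    design = sch.cox_design(pooled, schema)
    df = pd.concat([design, pooled[[surv.DURATION, surv.EVENT]]], axis=1)

    terms = surv.low_variance_filter(design, pooled[surv.EVENT],
                                     p.min_level_freq)
    terms = surv.vif_filter(design[terms], p.vif_threshold)
    terms = surv.univariate_screen(df, terms, alpha=p.alpha)
    if not terms:
        raise RuntimeError("no terms survived the univariate screen")
    fit = surv.fit_multivariate_cox(df, terms, l2=p.l2, alpha=p.alpha)
    ph_flags, fit = surv.test_proportional_hazards(fit, df, alpha=p.alpha)
    cv = surv.cross_validate_cindex(df, [t for t in fit.term_names
                                         if not t.endswith("__x_time")],
                                    l2=p.l2, folds=p.cv_folds,
                                    seed=config.seed)
    fit.cindex_cv = cv

    table = surv.hazard_table(fit)
    _write_csv(table, out / "hazard_table.csv")
    scores = surv.risk_scores(fit.base_betas, design)
    strat = surv.derive_strata(scores, pooled[surv.EVENT],
                               n_leaves=p.n_leaves, seed=config.seed)
    labels = surv.assign_stratum(scores.to_numpy(), strat)
    km = surv.km_validation(pooled.assign(**{surv.DURATION: pooled[surv.DURATION]}),
                            labels)
    strata_json = {"cutpoints": strat.cutpoints, "labels": strat.labels,
                   "ranges": strat.ranges, "cv_cutpoint_sd": strat.cv_cutpoint_sd,
                   "cindex_cv": cv, "ph_test": ph_flags}
    (out / "strata.json").write_text(json.dumps(strata_json, indent=2))
    curves = pd.concat([c.assign(stratum=g) for g, c in km.curves.items()],
                       ignore_index=True)
    _write_csv(curves, out / "km_curves.csv")
    lr = pd.DataFrame([{"group_a": a, "group_b": b, "chi2": t["chi2"],
                        "p": t["p"]}
                       for t in km.pairwise_tests
                       for a, b in [t["pair"]]])
    _write_csv(lr, out / "logrank.csv")
    pct = pd.DataFrame(km.percentiles).T.reset_index(names="stratum")
    _write_csv(pct.replace(np.inf, "not_reached"), out / "km_percentiles.csv")
    scored = pooled[["participant_id", surv.DURATION, surv.EVENT]].assign(
        risk_score=scores.to_numpy(), stratum=labels)
    _write_csv(scored, out / "risk_scores.csv")
    return {"artifacts": ["hazard_table.csv", "strata.json", "km_curves.csv",
                          "logrank.csv", "km_percentiles.csv",
                          "risk_scores.csv"],
            "rows": {"pooled": len(pooled), "model_terms": len(fit.terms)}}


def _stage_influence(config: PipelineConfig, schema, out: Path) -> dict:
    p = config.influence
    arch = infl.NetworkArchitecture(hidden_sizes=tuple(p.hidden_sizes),
                                    l2=p.l2, epochs=p.epochs)
    files = []
    mats = {}
    for name in ("healthy", "t2dm"):
        cohort = _read_cohort(out / f"clean_{name}.csv", schema)
        cohort = cohort.drop(columns=[c for c in sim.ID_COLS
                                      if c in cohort.columns])
        mat = infl.build_influence_matrix(
            cohort, schema, arch, runs=p.runs, folds=p.folds,
            seed=config.seed, variables=p.variables, cohort_label=name)
        mats[name] = mat
        f = f"influence_{name}.csv"
        _write_csv(mat.to_frame(), out / f)
        files.append(f)
        fs = f"influence_{name}_square.csv"
        _write_csv(mat.to_square(), out / fs, index=True)
        files.append(fs)
    diff = infl.difference_matrix(mats["t2dm"], mats["healthy"])
    _write_csv(diff, out / "difference_matrix.csv")
    files.append("difference_matrix.csv")
    return {"artifacts": files,
            "rows": {"pairs": len(mats["healthy"].estimates)}}


def _stage_network(config: PipelineConfig, schema, out: Path) -> dict:
    p = config.network
    rule = net.EdgeRule(threshold=p.edge_threshold, min_tier=p.min_tier)
    profiles = {}
    files = []
    for name in ("healthy", "t2dm"):
        mat = influence_from_frame(pd.read_csv(out / f"influence_{name}.csv"))
        g = net.build_network(mat, rule)
        nx_file = f"network_{name}.graphml"
        import networkx as nx
        nx.write_graphml(g, out / nx_file)
        files.append(nx_file)
        edges = pd.DataFrame(
            [{"source": u, "target": v, "weight": d["weight"],
              "tier": d["tier"]} for u, v, d in g.edges(data=True)])
        f = f"edges_{name}.csv"
        _write_csv(edges, out / f)
        files.append(f)
        profiles[name] = net.centrality_profile(g, cohort_label=name)
        f = f"centrality_{name}.csv"
        _write_csv(profiles[name].reset_index(), out / f)
        files.append(f)
    deltas = net.centrality_deltas(profiles["healthy"], profiles["t2dm"])
    _write_csv(deltas.reset_index(), out / "centrality_deltas.csv")
    files.append("centrality_deltas.csv")
    shift = net.vector_shift(profiles["healthy"], profiles["t2dm"],
                             theme_map=_node_theme_map(deltas.index))
    _write_csv(shift.reset_index(), out / "vector_shift.csv")
    files.append("vector_shift.csv")
    hz = pd.read_csv(out / "hazard_table.csv")
    node_map = _hazard_node_map(hz["term"], deltas.index)
    roles = net.classify_roles(deltas, hz, node_map=node_map)
    _write_csv(roles.reset_index(), out / "roles.csv")
    files.append("roles.csv")
    return {"artifacts": files, "rows": {"nodes": len(deltas)}}


def _node_theme_map(nodes) -> dict:
    out = {}
    for v in nodes:
        base = str(v).split("=")[0].split("[")[0]
        out[v] = DEFAULT_THEME_MAP.get(base, "other")
    return out


def _hazard_node_map(terms, nodes) -> dict:
    """Map hazard terms to network nodes; categorical terms to parent node."""
    nodes = set(nodes)
    mapping = {}
    for t in terms:
        base = t.split("[")[0]
        if t in nodes:
            mapping[t] = t
        elif base in nodes:
            mapping[t] = base
        else:
            # one-hot node naming: variable=level vs cox variable[level]
            if "[" in t:
                lev = t[t.index("[") + 1:-1]
                cand = f"{base}={lev}"
                if cand in nodes:
                    mapping[t] = cand
    return mapping


def _stage_report(config: PipelineConfig, schema, out: Path) -> dict:
    render_report(out, include_plots=config.include_plots)
    return {"artifacts": ["report.md"], "rows": {}}


_STAGE_FN = {
    "simulate": _stage_simulate, "preprocess": _stage_preprocess,
    "survival": _stage_survival, "influence": _stage_influence,
    "network": _stage_network, "report": _stage_report,
}


# ----------------------------------------------------------------------
def render_report(run_dir, include_plots: bool = True) -> Path:
    """Render a human-readable markdown summary of a completed run.

    Missing artifacts skip their section with a notice; regeneration is
    idempotent for identical inputs.
    """
    run = Path(run_dir)
    lines = ["# Behavioral risk & coherence analysis report", ""]

    def _section(title, fname, render):
        lines.append(f"## {title}")
        path = run / fname
        if not path.exists():
            lines.append(f"_Artifact `{fname}` not found; section skipped._")
            lines.append("")
            return
        render(path)
        lines.append("")

    def _table(path):
        df = pd.read_csv(path)
        lines.append(df.to_markdown(index=False, floatfmt=".3f"))

    _section("Hazard table", "hazard_table.csv", _table)

    def _strata(path):
        d = json.loads(path.read_text())
        lines.append(f"Cutpoints: {[round(c, 3) for c in d['cutpoints']]}")
        for lab, rng in d["ranges"].items():
            lines.append(f"- **{lab}**: {rng[0]} to {rng[1]}")
        if d.get("cindex_cv"):
            cv = d["cindex_cv"]
            lines.append(f"\nCross-validated C-index: {cv['mean']:.3f} "
                         f"(SD {cv['sd']:.3f})")
    _section("Risk strata", "strata.json", _strata)
    _section("Pairwise log-rank tests", "logrank.csv", _table)
    _section("Survival percentiles by stratum", "km_percentiles.csv", _table)
    _section("Influence matrix (healthy)", "influence_healthy.csv", _table)
    _section("Influence matrix (T2DM)", "influence_t2dm.csv", _table)
    _section("Difference matrix", "difference_matrix.csv", _table)
    _section("Centrality shifts", "centrality_deltas.csv", _table)
    _section("Role classification", "roles.csv", _table)

    if include_plots:
        try:
            _plots(run, lines)
        except Exception as exc:  # plotting must never break the report
            lines.append(f"_Plots skipped: {exc}_")

    report = run / "report.md"
    report.write_text("\n".join(lines))
    return report


def _plots(run: Path, lines: list):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    km = run / "km_curves.csv"
    if km.exists():
        df = pd.read_csv(km)
        fig, ax = plt.subplots(figsize=(6, 4))
        for g, sub in df.groupby("stratum"):
            ax.step(sub["time"], sub["survival"], where="post", label=str(g))
        ax.set_xlabel("years"), ax.set_ylabel("survival"), ax.legend()
        fig.savefig(run / "km_curves.png", dpi=100,
                    metadata={"Software": "behavnet"})
        plt.close(fig)
        lines.append("![KM curves](km_curves.png)")
    shift = run / "vector_shift.csv"
    if shift.exists():
        df = pd.read_csv(shift)
        fig, ax = plt.subplots(figsize=(6, 6))
        for _, r in df.iterrows():
            ax.annotate("", xy=(r["tip_x"], r["tip_y"]),
                        xytext=(r["base_x"], r["base_y"]),
                        arrowprops=dict(arrowstyle="->"))
        ax.set_xlabel("eigenvector"), ax.set_ylabel("betweenness")
        fig.savefig(run / "vector_shift.png", dpi=100,
                    metadata={"Software": "behavnet"})
        plt.close(fig)
        lines.append("![Vector shift](vector_shift.png)")
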