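"""Cohort cleaning and unsupervised outlier removal.

The cleaning chain runs in a fixed order: special-code recoding -> row
missingness filter -> typed imputation -> standardization -> embedding-based
outlier removal -> group balancing.  Recode and filter shrink the table;
imputation and standardization are row-preserving.

Outlier removal follows a multi-step unsupervised procedure: standardize,
project to two dimensions (t-SNE by default, PCA available for small
deterministic fixtures), choose the cluster count by silhouette score,
cluster the embedding with Ward linkage, and flag points beyond the 95th
percentile of Euclidean distance to their cluster centroid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from .schema import VariableSpec, numeric_design
from .simulate import ID_COLS

__all__ = [
    "OutlierReport",
    "recode_special_values",
    "filter_missing_rows",
    "impute",
    "standardize",
    "detect_outliers",
    "balance_downsample",
    "preprocess_cohorts",
]


# ----------------------------------------------------------------------
@dataclass
class OutlierReport:
    """Everything the outlier pipeline computed, for audit and export."""

    embedding: np.ndarray
    k_selected: int
    silhouette_by_k: dict
    cluster_labels: np.ndarray
    centroid_distances: np.ndarray
    threshold: dict           # cluster id -> 95th-percentile distance
    flagged_rows: np.ndarray  # positional indices

    def to_json(self) -> dict:
        d = asdict(self)
        d["embedding"] = np.asarray(self.embedding).tolist()
        d["cluster_labels"] = np.asarray(self.cluster_labels).tolist()
        d["centroid_distances"] = np.asarray(self.centroid_distances).tolist()
        d["flagged_rows"] = np.asarray(self.flagged_rows).tolist()
        d["silhouette_by_k"] = {int(k): float(v)
                                for k, v in self.silhouette_by_k.items()}
        d["threshold"] = {int(k): float(v) for k, v in self.threshold.items()}
        return d


# ----------------------------------------------------------------------
def recode_special_values(table: pd.DataFrame, schema: list[VariableSpec],
                          special_code_map: dict) -> pd.DataFrame:
    """Translate integer special codes into NaN or schema levels.

    ``special_code_map`` maps each code either to the string ``"missing"``
    ("don't know" / "prefer not to answer" style responses become NaN) or to
    a ``{variable_name: level}`` dict re-mapping order-breaking codes (e.g.
    a "none of the above" code) onto a legitimate level.
    """
    out = table.copy()
    by_name = {s.name: s for s in schema}
    for code, action in special_code_map.items():
        for name, spec in by_name.items():
            if name not in out.columns:
                continue
            # match numeric and string forms (CSV round-trips codes as text)
            mask = out[name].isin([code, str(code), float(code)])
            if not mask.any():
                continue
            if action == "missing":
                if not spec.is_continuous and code in spec.levels:
                    raise ValueError(
                        f"special code {code} collides with a level of {name}")
                out.loc[mask, name] = np.nan
            else:
                target = action.get(name)
                if target is None:
                    continue
                if target not in spec.levels:
                    raise ValueError(
                        f"recode target {target!r} is not a level of {name}")
                out.loc[mask, name] = target
    return out


def filter_missing_rows(table: pd.DataFrame, schema: list[VariableSpec],
                        threshold: float = 0.20
                        ) -> tuple[pd.DataFrame, int]:
    """Drop rows whose missing-cell share over schema columns exceeds threshold.

    The share is computed over predictor columns only (ids and outcome
    columns do not count), and the inequality is strict: exactly-at-threshold
    rows are kept.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    cols = [s.name for s in schema if s.name in table.columns]
    share = table[cols].isna().mean(axis=1)
    keep = share <= threshold
    return table.loc[keep].copy(), int((~keep).sum())


def impute(table: pd.DataFrame, schema: list[VariableSpec]) -> pd.DataFrame:
    """Single-value imputation per measurement scale.

    Continuous -> column mean; ordinal/nominal -> mode; binary -> the least
    frequent observed category (ties impute 0).  Raises if a column is
    entirely missing (no donor statistic exists).
    """
    out = table.copy()
    for spec in schema:
        if spec.name not in out.columns:
            continue
        col = out[spec.name]
        if not col.isna().any():
            continue
        obs = col.dropna()
        if obs.empty:
            raise ValueError(f"column {spec.name} entirely missing; cannot impute")
        if spec.is_continuous:
            fill = float(pd.to_numeric(obs).mean())
        elif spec.scale == "binary":
            counts = obs.value_counts()
            n0, n1 = counts.get(0, 0), counts.get(1, 0)
            fill = 0 if n0 <= n1 else 1  # least frequent; tie -> 0
        else:
            fill = obs.mode().iloc[0]
        out[spec.name] = col.fillna(fill)
    return out


def standardize(table: pd.DataFrame, schema: list[VariableSpec] | None = None
                ) -> pd.DataFrame:
    """Z-score a numeric matrix column-wise.

    If a schema is given, categorical columns are first expanded to a fully
    numeric design (continuous variables kept continuous).  Zero-variance
    columns pass through as zeros.
    """
    if schema is not None:
        num = numeric_design(table, schema)
    else:
        num = table.astype(float)
    mu = num.mean(axis=0)
    sd = num.std(axis=0, ddof=0)
    z = (num - mu).divide(sd.replace(0.0, 1.0), axis=1)
    z.loc[:, sd == 0.0] = 0.0
    return z


# ----------------------------------------------------------------------
def detect_outliers(matrix: pd.DataFrame | np.ndarray, *,
                    method: str = "tsne", perplexity: float = 40.0,
                    n_iter: int = 5000, k_range: range = range(2, 11),
                    percentile: float = 95.0, per_cluster: bool = True,
                    seed: int = 0) -> OutlierReport:
    """Silhouette k-selection + embedding + Ward clustering + distance flagging.

    The cluster count is selected first, on the standardized matrix itself:
    Ward linkage is cut at each k in ``k_range`` and the k with the highest
    silhouette score wins (ties -> smallest k).  The matrix is then
    projected to 2-D (t-SNE by default, honoring perplexity / iteration
    settings; PCA for small deterministic fixtures), the embedding is
    clustered with Ward at the selected k, and rows whose Euclidean distance
    to their cluster centroid lies beyond the given percentile are flagged
    (per cluster by default; globally with ``per_cluster=False``).
    """
    from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage

    X = np.asarray(matrix, dtype=float)
    n = len(X)
    if n <= max(k_range):
        raise ValueError(
            f"need more than {max(k_range)} rows for cluster search, got {n}")

    Z = scipy_linkage(X, method="ward")
    sil = {}
    for k in k_range:
        lab = fcluster(Z, k, criterion="maxclust")
        if len(np.unique(lab)) < 2:
            continue
        sil[k] = float(silhouette_score(X, lab))
    best = max(sil, key=lambda k: (sil[k], -k))

    if method == "tsne":
        if n <= 3 * perplexity:
            raise ValueError(
                f"n={n} is too small for perplexity={perplexity}; "
                "lower the perplexity or use method='pca'")
        emb = TSNE(n_components=2, perplexity=perplexity, max_iter=n_iter,
                   random_state=seed, init="pca").fit_transform(X)
    elif method == "pca":
        emb = PCA(n_components=2, random_state=seed).fit_transform(X)
    else:
        raise ValueError(f"unknown embedding method {method!r}")

    labels = AgglomerativeClustering(n_clusters=best,
                                     linkage="ward").fit_predict(emb)

    dist = np.empty(n)
    thr = {}
    flagged = []
    for c in np.unique(labels):
        m = labels == c
        centroid = emb[m].mean(axis=0)
        d = np.linalg.norm(emb[m] - centroid, axis=1)
        dist[m] = d
        if per_cluster:
            t = float(np.percentile(d, percentile))
            thr[int(c)] = t
            flagged.extend(np.flatnonzero(m)[d > t])
    if not per_cluster:
        t = float(np.percentile(dist, percentile))
        thr = {int(c): t for c in np.unique(labels)}
        flagged = list(np.flatnonzero(dist > t))

    return OutlierReport(
        embedding=emb, k_selected=int(best), silhouette_by_k=sil,
        cluster_labels=labels, centroid_distances=dist, threshold=thr,
        flagged_rows=np.array(sorted(flagged), dtype=int),
    )


def balance_downsample(healthy: pd.DataFrame, t2dm: pd.DataFrame,
                       seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Randomly down-sample the healthy group to the T2DM group size.

    Sampling is without replacement and unconditional on covariates.  The
    direction is fixed: the healthy pool must be at least as large as the
    T2DM cohort.
    """
    if len(healthy) < len(t2dm):
        raise ValueError(
            "healthy group smaller than T2DM group; balancing direction is "
            "healthy -> T2DM size")
    if len(healthy) == len(t2dm):
        return healthy.copy(), t2dm.copy()
    sub = healthy.sample(n=len(t2dm), replace=False,
                         random_state=seed).sort_index().reset_index(drop=True)
    return sub, t2dm.copy()


# ----------------------------------------------------------------------
def preprocess_cohorts(healthy: pd.DataFrame, t2dm: pd.DataFrame,
                       schema: list[VariableSpec], *,
                       special_code_map: dict | None = None,
                       missing_threshold: float = 0.20,
                       outlier_method: str = "tsne",
                       outlier_seed: int = 0,
                       joint_outliers: bool = True,
                       balance_seed: int = 0,
                       **outlier_kw) -> dict:
    """Run the full cleaning chain on a healthy/T2DM cohort pair.

    Returns a dict with the cleaned, balanced cohorts, per-stage row counts
    and the outlier reports.  Outlier detection is joint over both cohorts
    by default (``joint_outliers=False`` runs it per cohort).
    """
    special_code_map = special_code_map or {}
    log = {}
    frames = {}
    for name, df in (("healthy", healthy), ("t2dm", t2dm)):
        df = recode_special_values(df, schema, special_code_map)
        df, removed = filter_missing_rows(df, schema, missing_threshold)
        df = impute(df, schema)
        log[f"{name}_rows_removed_missing"] = removed
        frames[name] = df.reset_index(drop=True)

    reports = {}
    if joint_outliers:
        both = pd.concat([frames["healthy"], frames["t2dm"]],
                         ignore_index=True)
        z = standardize(both, schema)
        rep = detect_outliers(z, method=outlier_method, seed=outlier_seed,
                              **outlier_kw)
        reports["joint"] = rep
        n_h = len(frames["healthy"])
        flag = np.zeros(len(both), dtype=bool)
        flag[rep.flagged_rows] = True
        frames["healthy"] = frames["healthy"][~flag[:n_h]].reset_index(drop=True)
        frames["t2dm"] = frames["t2dm"][~flag[n_h:]].reset_index(drop=True)
        log["healthy_outliers_removed"] = int(flag[:n_h].sum())
        log["t2dm_outliers_removed"] = int(flag[n_h:].sum())
    else:
        for name in ("healthy", "t2dm"):
            z = standardize(frames[name], schema)
            rep = detect_outliers(z, method=outlier_method, seed=outlier_seed,
                                  **outlier_kw)
            reports[name] = rep
            keep = np.ones(len(frames[name]), dtype=bool)
            keep[rep.flagged_rows] = False
            log[f"{name}_outliers_removed"] = int((~keep).sum())
            frames[name] = frames[name][keep].reset_index(drop=True)

    if len(frames["healthy"]) < len(frames["t2dm"]):
        warnings.warn("healthy pool smaller than T2DM after cleaning; "
                      "skipping down-sampling")
    else:
        frames["healthy"], frames["t2dm"] = balance_downsample(
            frames["healthy"], frames["t2dm"], seed=balance_seed)
    log["healthy_final"] = len(frames["healthy"])
    log["t2dm_final"] = len(frames["t2dm"])
    return {"healthy": frames["healthy"], "t2dm": frames["t2dm"],
            "outlier_reports": reports, "log": log}
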