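"""Cox proportional-hazards risk modeling, scoring and stratification.

The model development pipeline follows standard epidemiological practice:

1. univariate screen — one single-term Cox fit per dummy-expanded predictor,
   retaining terms with p < alpha;
2. quality control — low-variance indicators (overall or within either event
   stratum) and high-collinearity columns (VIF > 10) are removed;
3. joint multivariate fit with a small L2 penalty and iterative backward
   refinement: the largest-p non-significant term is removed only when its
   removal leaves the remaining coefficients essentially unchanged and does
   not materially worsen the partial log-likelihood, with a refit at every
   step so reported estimates always come from the final term set;
4. proportional-hazards diagnostics via Schoenfeld residuals, with flagged
   terms refit carrying a covariate x time interaction;
5. internal validation by stratified cross-validated concordance.

Risk scores are the model's linear predictor sum_j beta_j x_ij; a five-leaf
decision tree on score vs incidence yields four cutpoints defining the
very-low .. very-high strata, validated with Kaplan-Meier curves, pairwise
log-rank tests and survival-time percentiles (with a "not reached" sentinel
when a curve never crosses the percentile threshold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, CoxTimeVaryingFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, proportional_hazard_test
from lifelines.utils import concordance_index, qth_survival_time
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "CoxFitResult",
    "RiskStratification",
    "KMValidation",
    "NOT_REACHED",
    "univariate_screen",
    "vif_filter",
    "low_variance_filter",
    "fit_multivariate_cox",
    "test_proportional_hazards",
    "cross_validate_cindex",
    "hazard_table",
    "hr_percent",
    "risk_score",
    "risk_scores",
    "derive_strata",
    "assign_stratum",
    "km_validation",
]

DURATION = "follow_up_years"
EVENT = "event"

#: sentinel for survival percentiles never reached during follow-up
NOT_REACHED = float("inf")

STRATUM_LABELS = ["very_low", "low", "moderate", "high", "very_high"]


# ----------------------------------------------------------------------
@dataclass
class CoxFitResult:
    """Fitted terms of the (final) multivariate Cox model."""

    terms: list                      # dicts: name, beta, se, hr, hr_pct, p, ci_low, ci_high
    time_interactions: list = field(default_factory=list)
    l2_penalty: float = 0.0
    cindex_cv: dict | None = None    # {'mean': .., 'sd': ..}
    model: object = None             # fitted lifelines object

    @property
    def betas(self) -> dict:
        return {t["name"]: t["beta"] for t in self.terms}

    @property
    def base_betas(self) -> dict:
        """Coefficients excluding covariate x time interaction terms."""
        return {t["name"]: t["beta"] for t in self.terms
                if t["name"] not in self.time_interactions}

    @property
    def term_names(self) -> list:
        return [t["name"] for t in self.terms]


def _fit_cox(df: pd.DataFrame, cols: list, l2: float) -> CoxPHFitter:
    cph = CoxPHFitter(penalizer=l2, l1_ratio=0.0)
    cph.fit(df[cols + [DURATION, EVENT]], duration_col=DURATION, event_col=EVENT)
    return cph


def _result_from_fitter(cph, cols, l2) -> CoxFitResult:
    s = cph.summary
    terms = []
    for name in cols:
        row = s.loc[name]
        beta = float(row["coef"])
        hr = float(np.exp(beta))
        terms.append({
            "name": name, "beta": beta, "se": float(row["se(coef)"]),
            "hr": hr, "hr_pct": (hr - 1.0) * 100.0, "p": float(row["p"]),
            "ci_low": float(np.exp(row["coef lower 95%"])),
            "ci_high": float(np.exp(row["coef upper 95%"])),
        })
    return CoxFitResult(terms=terms, l2_penalty=l2, model=cph)


# ----------------------------------------------------------------------
def univariate_screen(df: pd.DataFrame, terms: list, alpha: float = 0.05,
                      l2: float = 0.0) -> list:
    """Single-covariate Cox fit per term; keep terms with p < alpha.

    Terms whose fit fails to converge are dropped with a warning.
    """
    kept = []
    for t in terms:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph = _fit_cox(df, [t], l2)
            p = float(cph.summary.loc[t, "p"])
        except Exception as exc:  # convergence or degenerate column
            warnings.warn(f"univariate fit failed for {t}: {exc}; dropped")
            continue
        if p < alpha:
            kept.append(t)
    return kept


def vif_filter(design: pd.DataFrame, threshold: float = 10.0) -> list:
    """Iteratively drop the worst variance-inflation offender until all VIF <= threshold.

    VIF_j = 1 / (1 - R^2_j) with R^2_j from regressing column j (with an
    intercept) on the remaining columns.
    """
    cols = list(design.columns)
    if len(cols) < 2:
        return cols
    X = design.to_numpy(dtype=float)
    active = list(range(X.shape[1]))
    while len(active) > 1:
        vifs = []
        for j in active:
            others = [k for k in active if k != j]
            A = np.column_stack([np.ones(len(X)), X[:, others]])
            y = X[:, j]
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            resid = y - A @ coef
            ss_tot = np.sum((y - y.mean()) ** 2)
            r2 = 0.0 if ss_tot == 0 else 1.0 - np.sum(resid ** 2) / ss_tot
            r2 = min(r2, 1.0 - 1e-12)
            vifs.append(1.0 / (1.0 - r2))
        worst = int(np.argmax(vifs))
        if vifs[worst] <= threshold:
            break
        active.pop(worst)
    return [cols[j] for j in active]


def low_variance_filter(design: pd.DataFrame, events: pd.Series | np.ndarray,
                        min_level_freq: float = 0.01) -> list:
    """Drop indicator columns whose minority class is too rare.

    A column is dropped when its minority-class frequency falls below
    ``min_level_freq`` either overall or within either event stratum.
    Continuous (non-indicator) columns always pass.
    """
    events = np.asarray(events).astype(int)
    kept = []
    for c in design.columns:
        x = design[c].to_numpy(dtype=float)
        uniq = np.unique(x)
        if len(uniq) > 2:          # not an indicator
            kept.append(c)
            continue
        ok = True
        for mask in (np.ones(len(x), bool), events == 1, events == 0):
            sub = x[mask]
            if len(sub) == 0:
                ok = False
                break
            p1 = sub.mean() if set(uniq) <= {0.0, 1.0} else (sub == uniq[-1]).mean()
            if min(p1, 1.0 - p1) < min_level_freq:
                ok = False
                break
        if ok:
            kept.append(c)
    return kept


# ----------------------------------------------------------------------
def fit_multivariate_cox(df: pd.DataFrame, candidates: list,
                         l2: float = 1e-2, alpha: float = 0.05,
                         beta_change_tol: float = 0.10,
                         loglik_tol: float = 2.0,
                         stepwise: bool = True) -> CoxFitResult:
    """Joint Cox fit with iterative backward refinement.

    At each step the largest-p term with p >= alpha is removed provided the
    refit (i) changes each remaining coefficient by less than
    ``beta_change_tol`` relative (denominator floored at 0.1 on the
    log-hazard scale) and (ii) lowers the partial log-likelihood by less
    than ``loglik_tol``.  The model is refit after every removal so the
    reported estimates come from the final term set.
    """
    cols = list(candidates)
    if not cols:
        raise ValueError("no candidate terms to fit")
    cph = _fit_cox(df, cols, l2)
    while stepwise and len(cols) > 1:
        s = cph.summary
        weak = s.loc[[c for c in cols if s.loc[c, "p"] >= alpha]]
        if weak.empty:
            break
        removed = False
        for name in weak.sort_values("p", ascending=False).index:
            trial_cols = [c for c in cols if c != name]
            try:
                trial = _fit_cox(df, trial_cols, l2)
            except Exception:
                continue
            old = s.loc[trial_cols, "coef"]
            new = trial.summary.loc[trial_cols, "coef"]
            rel = (new - old).abs() / np.maximum(old.abs(), 0.1)
            ll_drop = float(cph.log_likelihood_ - trial.log_likelihood_)
            if (rel < beta_change_tol).all() and ll_drop < loglik_tol:
                cols, cph, removed = trial_cols, trial, True
                break
        if not removed:
            break
    return _result_from_fitter(cph, cols, l2)


# ----------------------------------------------------------------------
def _episode_split(df: pd.DataFrame, terms: list, flagged: list,
                   grid: float = 1.0) -> pd.DataFrame:
    """Long-format (start, stop] episodes on a yearly grid with x*t columns."""
    rows = []
    t_all = df[DURATION].to_numpy(float)
    e_all = df[EVENT].to_numpy(int)
    X = df[terms].to_numpy(float)
    for i in range(len(df)):
        t, e = t_all[i], e_all[i]
        cuts = np.arange(0.0, t, grid)
        starts = cuts
        stops = np.append(cuts[1:], t)
        keep = stops > starts
        starts, stops = starts[keep], stops[keep]
        for j, (a, b) in enumerate(zip(starts, stops)):
            rows.append((i, a, b, int(e) if j == len(starts) - 1 else 0,
                         *X[i]))
    long = pd.DataFrame(rows, columns=["pid", "start", "stop", EVENT] + terms)
    mid = (long["start"] + long["stop"]) / 2.0
    for name in flagged:
        long[f"{name}__x_time"] = long[name] * mid
    return long


def test_proportional_hazards(result: CoxFitResult, df: pd.DataFrame,
                              alpha: float = 0.05,
                              time_transform: str = "identity"
                              ) -> tuple[dict, CoxFitResult]:
    """Schoenfeld-residual PH test per term; refit flagged terms with x*t.

    Returns the per-term flag/p-value dict and a (possibly refitted) result.
    The refit uses an episode-split time-varying Cox model on a yearly grid,
    adding a covariate x time column for every flagged term.
    """
    cph = result.model
    test = proportional_hazard_test(
        cph, df[result.term_names + [DURATION, EVENT]],
        time_transform=time_transform)
    pvals = {}
    summ = test.summary
    for name in result.term_names:
        row = summ.loc[name]
        if isinstance(row, pd.DataFrame):
            row = row.iloc[0]
        pvals[name] = float(row["p"])
    flagged = [n for n, p in pvals.items() if p < alpha]
    flags = {"p": pvals, "flagged": flagged}
    if not flagged:
        return flags, result

    long = _episode_split(df, result.term_names, flagged)
    inter = [f"{n}__x_time" for n in flagged]
    ctv = CoxTimeVaryingFitter(penalizer=result.l2_penalty)
    ctv.fit(long[["pid", "start", "stop", EVENT] + result.term_names + inter],
            id_col="pid", event_col=EVENT, start_col="start", stop_col="stop")
    s = ctv.summary
    terms = []
    for name in result.term_names + inter:
        row = s.loc[name]
        beta = float(row["coef"])
        hr = float(np.exp(beta))
        terms.append({
            "name": name, "beta": beta, "se": float(row["se(coef)"]),
            "hr": hr, "hr_pct": (hr - 1.0) * 100.0, "p": float(row["p"]),
            "ci_low": float(np.exp(row["coef lower 95%"])),
            "ci_high": float(np.exp(row["coef upper 95%"])),
        })
    refit = CoxFitResult(terms=terms, time_interactions=inter,
                         l2_penalty=result.l2_penalty, model=ctv)
    return flags, refit


# ----------------------------------------------------------------------
def cross_validate_cindex(df: pd.DataFrame, terms: list, l2: float = 1e-2,
                          folds: int = 10, seed: int = 0) -> dict:
    """Out-of-sample concordance under event-stratified K-fold CV."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    ev = df[EVENT].to_numpy(int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = []
    for tr, te in skf.split(np.zeros(len(df)), ev):
        if ev[te].sum() == 0 or ev[tr].sum() == 0:
            raise ValueError("a fold has no events; use fewer folds")
        cph = _fit_cox(df.iloc[tr], terms, l2)
        lp = cph.predict_partial_hazard(df.iloc[te][terms])
        c = concordance_index(df.iloc[te][DURATION], -lp.to_numpy(),
                              df.iloc[te][EVENT])
        scores.append(c)
    return {"mean": float(np.mean(scores)), "sd": float(np.std(scores, ddof=1))}


# ----------------------------------------------------------------------
def hr_percent(hr: float) -> float:
    """Percent change in hazard from a (printed, two-decimal) hazard ratio."""
    return round((round(hr, 2) - 1.0) * 100.0, 2)


def hazard_table(result: CoxFitResult, rounding_policy: str = "table"
                 ) -> pd.DataFrame:
    """Printed-style hazard table: beta, exp(beta), HR%, p, CI bounds.

    Under the default ``table`` policy HR% derives from the HR rounded to
    two decimals, matching the convention of published tables; the ``exact``
    policy reports (exp(beta) - 1) x 100 unrounded.
    """
    rows = []
    for t in result.terms:
        beta = round(t["beta"], 2)
        hr = round(float(np.exp(t["beta"])), 2)
        if rounding_policy == "table":
            pct = round((hr - 1.0) * 100.0, 2)
        elif rounding_policy == "exact":
            pct = (np.exp(t["beta"]) - 1.0) * 100.0
        else:
            raise ValueError(f"unknown rounding policy {rounding_policy!r}")
        rows.append({"term": t["name"], "beta": beta, "hr": hr,
                     "hr_pct": pct, "p": t["p"],
                     "ci_low": round(t["ci_low"], 2),
                     "ci_high": round(t["ci_high"], 2)})
    return pd.DataFrame(rows)


def risk_score(betas: dict, covariate_row: dict) -> float:
    """Linear predictor sum_j beta_j x_ij for one encoded row.

    The row maps design-column names to values; columns at their reference
    level may simply be omitted (they contribute zero).  A row key that is
    not a model term raises.
    """
    unknown = [k for k in covariate_row if k not in betas]
    if unknown:
        raise KeyError(f"terms not in the model: {unknown}")
    return float(sum(betas[k] * v for k, v in covariate_row.items()))


def risk_scores(betas: dict, design: pd.DataFrame) -> pd.Series:
    """Vectorized linear predictor over a design matrix."""
    missing = [k for k in betas if k not in design.columns]
    if missing:
        raise KeyError(f"design lacks model terms: {missing}")
    lp = np.zeros(len(design))
    for k, b in betas.items():
        lp += b * design[k].to_numpy(float)
    return pd.Series(lp, index=design.index, name="risk_score")


# ----------------------------------------------------------------------
@dataclass
class RiskStratification:
    """Four ascending cutpoints defining the five risk strata."""

    cutpoints: list                  # 4 ascending reals (assignment boundaries)
    labels: list = field(default_factory=lambda: list(STRATUM_LABELS))
    ranges: dict = field(default_factory=dict)   # label -> [lo, hi] (printed style)
    cv_cutpoint_sd: list | None = None

    @classmethod
    def from_ranges(cls, ranges: dict) -> "RiskStratification":
        """Build assignment cutpoints as midpoints of the printed range gaps."""
        labels = list(ranges)
        cuts = []
        for a, b in zip(labels[:-1], labels[1:]):
            cuts.append((ranges[a][1] + ranges[b][0]) / 2.0)
        return cls(cutpoints=cuts, labels=labels,
                   ranges={k: list(v) for k, v in ranges.items()})


def derive_strata(scores: np.ndarray | pd.Series, events: np.ndarray | pd.Series,
                  n_leaves: int = 5, folds: int = 10, seed: int = 0,
                  min_leaf_fraction: float = 0.10) -> RiskStratification:
    """Supervised discretization of the risk score into ``n_leaves`` strata.

    A single-feature decision tree (Gini impurity, leaf cap) on score vs
    observed incidence supplies the split thresholds, which are sorted and
    frozen as the cutpoints.  Each leaf must hold at least
    ``min_leaf_fraction`` of participants so every stratum's incidence is
    estimated on a stable sample.  Cross-validation re-derives the
    thresholds per fold to report their stability (standard deviation per
    cutpoint); it does not re-select them.
    """
    s = np.asarray(scores, dtype=float)
    e = np.asarray(events, dtype=int)
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    if len(np.unique(s)) < n_leaves:
        raise ValueError(f"need at least {n_leaves} distinct scores")

    def _cuts(sv, ev):
        tree = DecisionTreeClassifier(max_leaf_nodes=n_leaves,
                                      min_samples_leaf=min_leaf_fraction,
                                      random_state=seed)
        tree.fit(sv.reshape(-1, 1), ev)
        t = tree.tree_
        return np.sort(t.threshold[t.feature == 0])

    cuts = _cuts(s, e)
    sd = None
    if folds >= 2 and e.sum() >= folds and (1 - e).sum() >= folds:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        per_fold = []
        for tr, _ in skf.split(s.reshape(-1, 1), e):
            c = _cuts(s[tr], e[tr])
            if len(c) == len(cuts):
                per_fold.append(c)
        if per_fold:
            sd = np.std(np.vstack(per_fold), axis=0, ddof=0).tolist()

    labels = (list(STRATUM_LABELS) if n_leaves == 5
              else [f"stratum_{i}" for i in range(n_leaves)])
    bounds = [float(s.min())] + list(cuts) + [float(s.max())]
    ranges = {}
    for i, lab in enumerate(labels):
        lo = round(bounds[i], 2) if i == 0 else round(bounds[i], 2) + 0.01
        hi = round(bounds[i + 1], 2)
        ranges[lab] = [lo, hi]
    return RiskStratification(cutpoints=[float(c) for c in cuts],
                              labels=labels, ranges=ranges,
                              cv_cutpoint_sd=sd)


def assign_stratum(score, stratification: RiskStratification):
    """Label of the interval containing the score.

    Boundaries are half-open at the cutpoints (a score equal to a cutpoint
    belongs to the upper stratum, i.e. the midpoint-of-gap policy for
    printed two-decimal ranges).  Scores outside the global span clamp to
    the end strata with a warning.
    """
    cuts = np.asarray(stratification.cutpoints, dtype=float)
    arr = np.atleast_1d(np.asarray(score, dtype=float))
    lo = min(r[0] for r in stratification.ranges.values()) if stratification.ranges else -np.inf
    hi = max(r[1] for r in stratification.ranges.values()) if stratification.ranges else np.inf
    if ((arr < lo - 0.01) | (arr > hi + 0.01)).any():
        warnings.warn("score outside the observed span; clamped to end strata")
    idx = np.searchsorted(cuts, arr, side="right")
    labels = np.asarray(stratification.labels, dtype=object)[idx]
    if np.isscalar(score) or np.asarray(score).ndim == 0:
        return labels[0]
    return labels


# ----------------------------------------------------------------------
@dataclass
class KMValidation:
    """Kaplan-Meier curves, pairwise log-rank tests and survival percentiles."""

    curves: dict                     # label -> DataFrame(time, survival, at_risk)
    pairwise_tests: list             # dicts: pair, chi2, p
    percentiles: dict                # label -> {p25, p50, p75}; inf = not reached


def km_validation(df: pd.DataFrame, labels: np.ndarray | pd.Series,
                  duration_col: str = DURATION, event_col: str = EVENT
                  ) -> KMValidation:
    """Per-stratum product-limit curves with pairwise log-rank comparison.

    Empty strata are excluded with a warning.  Percentiles use the
    ``NOT_REACHED`` (infinity) sentinel when a curve never falls below the
    percentile threshold during follow-up.
    """
    labels = pd.Series(np.asarray(labels, dtype=object), index=df.index)
    present = [g for g in pd.unique(labels) if (labels == g).sum() > 0]
    if len(present) < 2:
        raise ValueError("need at least two non-empty strata")
    curves, percentiles = {}, {}
    fitters = {}
    for g in present:
        sub = df[labels == g]
        if sub.empty:
            warnings.warn(f"stratum {g} empty; excluded")
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(sub[duration_col], sub[event_col], label=str(g))
        fitters[g] = kmf
        sf = kmf.survival_function_
        at_risk = kmf.event_table["at_risk"].reindex(sf.index).ffill()
        curves[g] = pd.DataFrame({
            "time": sf.index.to_numpy(float),
            "survival": sf.iloc[:, 0].to_numpy(float),
            "at_risk": at_risk.to_numpy(float),
        })
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # lifelines grid approximation
            percentiles[g] = {
                "p25": float(qth_survival_time(0.75, kmf)),
                "p50": float(qth_survival_time(0.50, kmf)),
                "p75": float(qth_survival_time(0.25, kmf)),
            }
    tests = []
    keys = list(fitters)
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            a, b = keys[i], keys[j]
            da, db = df[labels == a], df[labels == b]
            res = logrank_test(da[duration_col], db[duration_col],
                               da[event_col], db[event_col])
            tests.append({"pair": (a, b), "chi2": float(res.test_statistic),
                          "p": float(res.p_value)})
    return KMValidation(curves=curves, pairwise_tests=tests,
                        percentiles=percentiles)
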