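"""ANN-derived variable-to-variable influence estimation.

For every selected target variable a two-hidden-layer feedforward network
(ReLU; 64 and 32 units by default) is trained to predict that variable from
all other encoded predictors, with an output head matched to the target's
scale (sigmoid/cross-entropy for binary, linear/squared error for
continuous, softmax for grouped categorical targets).  Training repeats over
``runs`` independent shuffles x ``folds`` cross-validation folds, yielding
``runs x folds`` networks per target.

The systemic influence of input i on output o is the *effective weight*:
the sum over all hidden paths of the product of connection weights,

    W_eff[i, o] = sum_{h1} sum_{h2} w[i, h1] * w[h1, h2] * w[h2, o],

which equals the (i, o) entry of the ordered product of the three weight
matrices (biases excluded).  Signed effective weights are aggregated over
the ensemble by the median, and *sign stability* — the share of ensemble
members agreeing on the sign — is tiered:

* highly stable:      >= 70% same-sign
* moderately stable:  60-69%
* low stability:      < 60%
* unstable:           approximately even split (within 2 points of 50/50)

Per-cohort influence matrices hold one estimate per ordered variable pair;
subtracting the healthy matrix from the disease-state matrix gives the
difference matrix whose sign reversals mark reorganized relationships.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPClassifier, MLPRegressor

from .schema import VariableSpec

__all__ = [
    "NetworkArchitecture",
    "InfluenceEstimate",
    "InfluenceMatrix",
    "encode_for_ann",
    "train_target_networks",
    "effective_weights",
    "aggregate_influence",
    "build_influence_matrix",
    "difference_matrix",
]

TIERS = ("highly_stable", "moderately_stable", "low_stability", "unstable")


# ----------------------------------------------------------------------
@dataclass
class NetworkArchitecture:
    """Hyperparameters of the per-target feedforward networks.

    Two hidden ReLU layers are fixed by design; their widths, the L2
    penalty, and the optimization settings (adaptive-moment optimizer,
    epoch cap with early stopping on a held-out validation split) are
    tunable.
    """

    hidden_sizes: tuple = (64, 32)
    l2: float = 1e-4
    epochs: int = 200
    batch_size: int = 64
    learning_rate: float = 1e-3
    early_stopping: bool = True
    patience: int = 20

    def __post_init__(self):
        if len(self.hidden_sizes) != 2:
            raise ValueError("architecture is fixed at two hidden layers")

    def _common_kw(self, n_rows: int, random_state: int) -> dict:
        return dict(
            hidden_layer_sizes=tuple(self.hidden_sizes),
            activation="relu", solver="adam", alpha=self.l2,
            batch_size=min(self.batch_size, n_rows),
            learning_rate_init=self.learning_rate,
            max_iter=self.epochs,
            early_stopping=self.early_stopping and n_rows >= 50,
            n_iter_no_change=self.patience,
            random_state=random_state,
        )


@dataclass
class InfluenceEstimate:
    """Median effective weight of one input on one target, with stability."""

    input: str
    target: str
    median_weight: float
    pct_positive: float
    pct_negative: float
    tier: str


@dataclass
class InfluenceMatrix:
    """Directed input -> target influence grid for one cohort."""

    variables: list
    estimates: dict            # (input, target) -> InfluenceEstimate
    cohort_label: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "input": e.input, "target": e.target,
            "median_weight": e.median_weight,
            "pct_positive": e.pct_positive, "pct_negative": e.pct_negative,
            "tier": e.tier, "cohort": self.cohort_label,
        } for e in self.estimates.values()]
        return pd.DataFrame(rows)

    def to_square(self) -> pd.DataFrame:
        m = pd.DataFrame(np.nan, index=self.variables, columns=self.variables)
        for (i, t), e in self.estimates.items():
            m.loc[i, t] = e.median_weight
        return m


# ----------------------------------------------------------------------
def encode_for_ann(cohort: pd.DataFrame, schema: list[VariableSpec]
                   ) -> tuple[pd.DataFrame, dict]:
    """Encode a cohort for network training.

    Continuous variables are min–max scaled to [0, 1]; binary variables pass
    through; variables with an ``ann_collapse`` rule become a single
    indicator (``top_level``: membership in the top intake band, i.e. the
    two highest frequency levels; ``ever``: any non-reference level);
    nominal/ordinal one-hot variables expand to one column per level.

    Returns the feature matrix and a per-variable descriptor mapping
    variable name -> {'type': 'binary'|'continuous'|'categorical',
    'columns': [...], 'levels': [...]}.
    """
    cols, desc = {}, {}
    for spec in schema:
        if spec.name not in cohort.columns:
            continue
        x = cohort[spec.name]
        if spec.ann_encoding == "minmax_continuous":
            v = pd.to_numeric(x).to_numpy(float)
            lo, hi = np.nanmin(v), np.nanmax(v)
            rng = hi - lo if hi > lo else 1.0
            cols[spec.name] = (v - lo) / rng
            desc[spec.name] = {"type": "continuous", "columns": [spec.name],
                               "levels": []}
        elif spec.ann_encoding == "binary_indicator":
            if spec.ann_collapse == "top_level":
                pos = set(spec.levels[-2:])
                cols[spec.name] = x.isin(pos).astype(float).to_numpy()
            elif spec.ann_collapse == "ever":
                cols[spec.name] = (x != spec.reference_level).astype(float).to_numpy()
            else:
                one = spec.levels[-1] if spec.levels else 1
                cols[spec.name] = (x == one).astype(float).to_numpy()
            desc[spec.name] = {"type": "binary", "columns": [spec.name],
                               "levels": []}
        elif spec.ann_encoding == "one_hot":
            names = []
            for lev in spec.levels:
                c = f"{spec.name}={lev}"
                cols[c] = (x == lev).astype(float).to_numpy()
                names.append(c)
            desc[spec.name] = {"type": "categorical", "columns": names,
                               "levels": list(spec.levels)}
        else:
            raise ValueError(f"cannot encode {spec.name} ({spec.ann_encoding})")
    return pd.DataFrame(cols, index=cohort.index), desc


def _member_seed(seed: int, run: int, fold: int) -> int:
    return int((seed * 1_000_003 + run * 1_009 + fold * 101) % (2**31 - 1))


def train_target_networks(features: pd.DataFrame, target: np.ndarray,
                          head: str, arch: NetworkArchitecture,
                          runs: int = 10, folds: int = 5, seed: int = 0
                          ) -> list:
    """Train the runs x folds ensemble for one target.

    ``head`` is ``'binary'``, ``'continuous'`` or ``'categorical'``.  Each
    member trains on the fold's training split; weights (the three
    connection matrices, biases excluded) are collected.  Members with
    non-finite weights are re-initialized once and otherwise skipped with a
    warning; binary/categorical members whose training split is single-class
    are skipped.
    """
    X = features.to_numpy(float)
    y = np.asarray(target)
    out = []
    for run in range(runs):
        kf = KFold(n_splits=folds, shuffle=True,
                   random_state=_member_seed(seed, run, folds + 1))
        for fold, (tr, _) in enumerate(kf.split(X)):
            rs = _member_seed(seed, run, fold)
            Xt, yt = X[tr], y[tr]
            if head in ("binary", "categorical") and len(np.unique(yt)) < 2:
                warnings.warn("single-class training split; member skipped")
                continue
            for attempt in range(2):
                kw = arch._common_kw(len(Xt), rs + attempt)
                model = (MLPRegressor(**kw) if head == "continuous"
                         else MLPClassifier(**kw))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model.fit(Xt, yt)
                W = [np.array(w, dtype=float) for w in model.coefs_]
                if all(np.isfinite(w).all() for w in W):
                    out.append(tuple(W))
                    break
            else:
                warnings.warn("non-finite weights after re-init; member skipped")
    return out


def effective_weights(weight_set) -> np.ndarray:
    """Path-product effective weights: the chained product of the 3 matrices.

    Returns an (n_inputs, n_outputs) array; equals the brute-force sum over
    all (h1, h2) paths of w[i,h1] * w[h1,h2] * w[h2,o].
    """
    W0, W1, W2 = weight_set
    if W0.shape[1] != W1.shape[0] or W1.shape[1] != W2.shape[0]:
        raise ValueError("weight matrices are not conformable")
    return W0 @ W1 @ W2


def aggregate_influence(samples, input_name: str = "", target_name: str = "",
                        unstable_band: float = 2.0) -> InfluenceEstimate:
    """Median and sign-stability summary of one input->target ensemble.

    Exactly-zero effective weights are counted toward the smaller sign class
    (conservative for stability); on a tie they are split as evenly as
    possible.  The tier derives from max(pct_positive, pct_negative):
    >=70 highly stable, 60-69 moderately stable, otherwise low stability,
    except an approximately even split (within ``unstable_band`` points of
    50) which is unstable.
    """
    v = np.asarray(samples, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 ensemble members")
    pos = int((v > 0).sum())
    neg = int((v < 0).sum())
    zeros = len(v) - pos - neg
    if zeros:
        if pos < neg:
            pos += zeros
        elif neg < pos:
            neg += zeros
        else:
            pos += zeros - zeros // 2
            neg += zeros // 2
    pct_pos = 100.0 * pos / len(v)
    pct_neg = 100.0 * neg / len(v)
    m = max(pct_pos, pct_neg)
    if m <= 50.0 + unstable_band:
        tier = "unstable"
    elif m >= 70.0:
        tier = "highly_stable"
    elif m >= 60.0:
        tier = "moderately_stable"
    else:
        tier = "low_stability"
    return InfluenceEstimate(input=input_name, target=target_name,
                             median_weight=float(np.median(v)),
                             pct_positive=pct_pos, pct_negative=pct_neg,
                             tier=tier)


# ----------------------------------------------------------------------
def _reduce_multiclass(eff: np.ndarray, how: str = "max_magnitude") -> np.ndarray:
    """Collapse per-class effective weights to one signed value per input."""
    if eff.shape[1] == 1:
        return eff[:, 0]
    if how == "max_magnitude":
        idx = np.argmax(np.abs(eff), axis=1)
        return eff[np.arange(len(eff)), idx]
    if how == "sum":
        return eff.sum(axis=1)
    raise ValueError(f"unknown reduction {how!r}")


def build_influence_matrix(cohort: pd.DataFrame, schema: list[VariableSpec],
                           arch: NetworkArchitecture | None = None, *,
                           runs: int = 10, folds: int = 5, seed: int = 0,
                           variables: list | None = None,
                           grouped_targets: bool = False,
                           multiclass_reduction: str = "max_magnitude",
                           cohort_label: str = "",
                           unstable_band: float = 2.0) -> InfluenceMatrix:
    """Loop every selected variable as target; assemble the influence grid.

    By default every encoded feature column is a network node (level-specific
    nodes for one-hot variables, matching how dietary types are reported);
    ``variables`` restricts the node set.  With ``grouped_targets`` one-hot
    blocks are instead predicted jointly through a softmax head and the
    per-class effective weights are reduced to one signed value
    (``max_magnitude`` by default, ``sum`` optionally).

    Outcome and follow-up columns must already be absent from ``cohort``'s
    schema variables; only covariates listed in the schema are encoded.
    """
    arch = arch or NetworkArchitecture()
    features, desc = encode_for_ann(cohort, schema)
    if variables is None:
        nodes = (list(desc) if grouped_targets else list(features.columns))
    else:
        nodes = list(variables)

    col_of = {}
    for name, d in desc.items():
        col_of[name] = d["columns"]
    estimates = {}
    for tgt in nodes:
        if grouped_targets:
            d = desc[tgt]
            tgt_cols = d["columns"]
            if d["type"] == "categorical":
                head = "categorical"
                y = cohort[tgt].to_numpy()
            elif d["type"] == "continuous":
                head, y = "continuous", features[tgt].to_numpy()
            else:
                head, y = "binary", features[tgt].to_numpy().astype(int)
        else:
            tgt_cols = [tgt]
            owner = next(n for n, d in desc.items() if tgt in d["columns"])
            head = "continuous" if desc[owner]["type"] == "continuous" else "binary"
            y = features[tgt].to_numpy()
            if head == "binary":
                y = y.astype(int)
        X = features.drop(columns=tgt_cols)
        ensemble = train_target_networks(X, y, head, arch, runs=runs,
                                         folds=folds, seed=seed)
        if len(ensemble) < 2:
            warnings.warn(f"target {tgt}: fewer than 2 trained members; skipped")
            continue
        eff = np.stack([_reduce_multiclass(effective_weights(w),
                                           multiclass_reduction)
                        for w in ensemble])          # (members, n_inputs)
        for j, inp in enumerate(X.columns):
            if grouped_targets:
                owner_in = next(n for n, d in desc.items() if inp in d["columns"])
                key_in = inp if desc[owner_in]["type"] == "categorical" else owner_in
            else:
                key_in = inp
            if variables is not None and key_in not in nodes:
                continue
            if key_in == tgt:
                continue
            estimates[(key_in, tgt)] = aggregate_influence(
                eff[:, j], key_in, tgt, unstable_band=unstable_band)
    return InfluenceMatrix(variables=nodes, estimates=estimates,
                           cohort_label=cohort_label)


def difference_matrix(t2dm: InfluenceMatrix, healthy: InfluenceMatrix
                      ) -> pd.DataFrame:
    """Elementwise T2DM minus healthy median influences, with reversal flags.

    Returns a long-format frame with the signed difference, its absolute
    value, and a flag marking pairs whose medians have opposite signs in
    the two cohorts.
    """
    if set(t2dm.estimates) != set(healthy.estimates):
        raise ValueError("influence matrices cover different variable pairs")
    rows = []
    for key in t2dm.estimates:
        a = t2dm.estimates[key].median_weight
        b = healthy.estimates[key].median_weight
        rows.append({
            "input": key[0], "target": key[1],
            "healthy": b, "t2dm": a,
            "difference": a - b, "abs_difference": abs(a - b),
            "sign_reversal": bool(a * b < 0),
        })
    return pd.DataFrame(rows)
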