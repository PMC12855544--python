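"""Synthetic behavioral survival cohorts.

Generates participant tables with the statistical structure the downstream
analysis assumes: typed covariates drawn per the schema, event times from a
Weibull-baseline proportional-hazards model, random plus administrative
censoring, injected missingness (including integer special codes) and
injected multivariate outliers with ground truth.

The event-time model is

    h(t | x) = h0(t) * exp(sum_j beta_j x_j),      h0 Weibull(shape k, scale s)

with survival S(t|x) = exp(-(t/s)^k * exp(lp)), sampled by inverse transform:

    T = s * (-log(U) * exp(-lp))^(1/k),   U ~ Uniform(0, 1).

Times below one year are resampled so follow-up spans [1, max_follow] years.
Participants whose event time exceeds their censoring time contribute a
censored record; the generator labels event rows ``t2dm`` and censored rows
``healthy``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .schema import VariableSpec, cox_design, default_schema
from .reference import REFERENCE_BETAS

__all__ = [
    "GeneratorConfig",
    "simulate_covariates",
    "simulate_survival",
    "generate_cohort_pair",
    "inject_missingness",
    "inject_outliers",
]

#: columns that are bookkeeping, never part of the predictor schema
ID_COLS = ("participant_id", "event", "follow_up_years", "cohort_label")


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort generator.

    ``betas`` maps Cox design column names to log-hazard coefficients
    (defaults to the reference coefficient set).  ``baseline_shape`` /
    ``baseline_scale`` parameterize the Weibull baseline hazard; the default
    scale is calibrated so a high-risk profile (linear predictor ~0.9) has
    about a 50% cumulative event probability by the 17-year administrative
    cutoff.
    """

    n_per_group: int = 1000
    healthy_surplus: float = 0.2
    betas: Optional[dict] = None
    baseline_shape: float = 1.2
    baseline_scale: float = 50.0
    max_follow: float = 17.0
    censor_uniform: bool = True
    latent_correlation: float = 0.8
    missing_row_fraction: float = 0.0
    missing_cell_rate: float = 0.0
    special_code_map: dict = field(
        default_factory=lambda: {-1: "missing", -3: "missing"}
    )
    special_code_share: float = 0.3
    outlier_fraction: float = 0.0
    outlier_scale: float = 8.0
    seed: int = 0

    def __post_init__(self):
        for name in ("missing_row_fraction", "missing_cell_rate",
                     "outlier_fraction", "special_code_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.baseline_shape <= 0 or self.baseline_scale <= 0:
            raise ValueError("baseline shape and scale must be positive")

    def resolved_betas(self) -> dict:
        return dict(REFERENCE_BETAS) if self.betas is None else dict(self.betas)


#: behavioral-domain latent factor per variable: (factor index, loading).
#: Psychosocial/sleep/lifestyle variables share a "distress" factor; dietary
#: variables and BMI share a "diet quality" factor; age stays independent.
DEFAULT_FACTOR_MAP: dict[str, tuple[int, float]] = {
    "loneliness_isolation": (0, 0.9), "seen_psychiatrist": (0, 0.9),
    "sleeplessness_insomnia": (0, 0.9), "fed_up_feelings": (0, 0.9),
    "tense_highly_strung": (0, 0.9), "sleep_duration_7_8h": (0, -0.9),
    "nap_during_day": (0, 0.9), "difficulty_getting_up": (0, 0.9),
    "plays_computer_games": (0, 0.5), "current_tobacco_smoking": (0, 0.5),
    "smoking_status": (0, 0.5), "age": (0, 0.4),
    "salt_added_to_food": (1, 0.9), "cheese_intake": (1, -0.5),
    "bread_type": (1, 0.9), "cereal_type": (1, 0.9),
    "processed_meat_intake": (1, 0.9), "beef_intake": (1, 0.9),
    "bmi": (1, 0.5),
}

#: the distress factor is a balanced two-component normal mixture (two broad
#: behavioral "types"), which is what gives the pooled standardized data its
#: characteristic two-cluster geometry; component centers +-delta, within-
#: component spread sigma.
BIMODAL_DELTA = 1.2
BIMODAL_SIGMA = 0.3


def _mixture_cdf(z: np.ndarray, rho: float) -> np.ndarray:
    """Exact CDF of rho*u0 + sqrt(1-rho^2)*eps with bimodal u0.

    Used as the copula marginal transform so that level probabilities are
    preserved exactly despite the non-normal factor.
    """
    from scipy.stats import norm
    tau = np.sqrt(rho ** 2 * BIMODAL_SIGMA ** 2 + 1.0 - rho ** 2)
    mu = rho * BIMODAL_DELTA
    return 0.5 * (norm.cdf((z - mu) / tau) + norm.cdf((z + mu) / tau))


def _draw_factors(rng: np.random.Generator, n: int, n_factors: int
                  ) -> np.ndarray:
    u = rng.standard_normal((n, n_factors))
    comp = rng.choice([-1.0, 1.0], size=n)
    u[:, 0] = comp * BIMODAL_DELTA + BIMODAL_SIGMA * u[:, 0]
    return u


def _values_from_latent(schema, z_by_var: dict, latent_correlation: float,
                        fmap: dict) -> dict:
    """Map per-variable latent normals to schema values via marginal CDFs."""
    from scipy.stats import norm
    cols = {}
    for spec in schema:
        z = z_by_var[spec.name]
        f, load = fmap.get(spec.name, (0, 0.0))
        rho = float(np.clip(latent_correlation * load, -0.99, 0.99))
        p = _mixture_cdf(z, rho) if f == 0 else norm.cdf(z)
        if spec.is_continuous:
            lo, hi = spec.gen_params["range"]
            cols[spec.name] = lo + p * (hi - lo)
        else:
            probs = spec.gen_params.get("probs")
            if probs is None:
                probs = [1.0 / len(spec.levels)] * len(spec.levels)
            cum = np.cumsum(probs)
            idx = np.minimum(np.searchsorted(cum, p, side="right"),
                             len(spec.levels) - 1)
            vals = np.asarray(spec.levels, dtype=object)[idx]
            cols[spec.name] = (vals.astype(int) if spec.scale == "binary"
                               else vals)
    return cols


def simulate_covariates(schema: list[VariableSpec], n: int,
                        seed: int | np.random.Generator = 0,
                        latent_correlation: float = 0.0,
                        factor_map: dict | None = None) -> pd.DataFrame:
    """Draw ``n`` rows of covariates with the schema's marginal distributions.

    With ``latent_correlation == 0`` every variable is drawn independently:
    categorical variables from their level probabilities, continuous
    variables uniformly on their range.  A positive ``latent_correlation``
    activates a Gaussian-copula dependence structure: per-row latent domain
    factors (a bimodal distress factor and a diet-quality factor) shift each
    variable's latent normal by ``latent_correlation x loading`` before it
    is mapped through the variable's marginal quantile function, giving
    realistic within-domain correlation and a two-cluster population
    geometry while preserving every marginal exactly.  Reproducible under a
    fixed seed.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    fmap = DEFAULT_FACTOR_MAP if factor_map is None else factor_map
    n_factors = 1 + max((f for f, _ in fmap.values()), default=0)
    u = _draw_factors(rng, n, n_factors)
    z_by_var = {}
    for spec in schema:
        f, load = fmap.get(spec.name, (0, 0.0))
        rho = float(np.clip(latent_correlation * load, -0.99, 0.99))
        z_by_var[spec.name] = (rho * u[:, f]
                               + np.sqrt(1.0 - rho ** 2) * rng.standard_normal(n))
    cols = {"participant_id": np.arange(n, dtype=int)}
    cols.update(_values_from_latent(schema, z_by_var, latent_correlation, fmap))
    return pd.DataFrame(cols)


def _linear_predictor(covariates: pd.DataFrame, schema: list[VariableSpec],
                      betas: dict) -> np.ndarray:
    design = cox_design(covariates, schema)
    missing = [t for t in betas if t not in design.columns]
    if missing:
        raise ValueError(
            f"beta terms not resolvable against the Cox design: {missing}"
        )
    lp = np.zeros(len(design))
    for term, b in betas.items():
        lp += b * design[term].to_numpy()
    return lp


def simulate_survival(covariates: pd.DataFrame, config: GeneratorConfig,
                      schema: Optional[list[VariableSpec]] = None,
                      seed: int | np.random.Generator | None = None) -> pd.DataFrame:
    """Attach event indicator, follow-up time and cohort label to covariates.

    Event times are drawn from the Weibull proportional-hazards model;
    censoring is the minimum of an optional uniform censoring time on
    [1, max_follow] and the administrative cutoff.  Event and censoring
    times below one year are resampled.
    """
    schema = default_schema() if schema is None else schema
    if seed is None:
        seed = config.seed
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    betas = config.resolved_betas()
    lp = _linear_predictor(covariates, schema, betas)
    n = len(covariates)
    k, s = config.baseline_shape, config.baseline_scale

    # inverse-transform sampling, resampling any time below 1 year
    T = np.empty(n)
    todo = np.ones(n, dtype=bool)
    while todo.any():
        u = rng.uniform(size=todo.sum())
        T[todo] = s * (-np.log(u) * np.exp(-lp[todo])) ** (1.0 / k)
        todo = T < 1.0

    if config.censor_uniform:
        C = rng.uniform(1.0, config.max_follow, size=n)
    else:
        C = np.full(n, config.max_follow)
    C = np.minimum(C, config.max_follow)

    event = (T <= C).astype(int)
    follow = np.minimum(T, C)

    out = covariates.copy()
    out["event"] = event
    out["follow_up_years"] = follow
    out["cohort_label"] = np.where(event == 1, "t2dm", "healthy")
    return out


def generate_cohort_pair(config: GeneratorConfig,
                         schema: Optional[list[VariableSpec]] = None
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (healthy, t2dm) cohorts; healthy carries a surplus.

    The censored (healthy) group is ``n_per_group * (1 + healthy_surplus)``
    rows so that downstream cleaning can drop rows and still down-sample
    healthy to the T2DM size, mirroring how such cohorts are derived.
    Draws covariate+survival batches until both groups are filled, then
    truncates to the requested sizes; deterministic given the config seed.
    """
    schema = default_schema() if schema is None else schema
    rng = np.random.default_rng(config.seed)
    n_healthy = int(round(config.n_per_group * (1.0 + config.healthy_surplus)))
    healthy, t2dm = [], []
    n_h = n_t = 0
    offset = 0
    while n_h < n_healthy or n_t < config.n_per_group:
        batch = max(2 * config.n_per_group, 500)
        cov = simulate_covariates(schema, batch, rng,
                                  latent_correlation=config.latent_correlation)
        cov["participant_id"] += offset
        offset += batch
        sim = simulate_survival(cov, config, schema, rng)
        h = sim[sim["event"] == 0]
        t = sim[sim["event"] == 1]
        healthy.append(h)
        t2dm.append(t)
        n_h += len(h)
        n_t += len(t)
    healthy = pd.concat(healthy).head(n_healthy).reset_index(drop=True)
    t2dm = pd.concat(t2dm).head(config.n_per_group).reset_index(drop=True)
    return healthy, t2dm


def _schema_cols(table: pd.DataFrame, schema: list[VariableSpec]) -> list:
    return [s.name for s in schema if s.name in table.columns]


def inject_missingness(table: pd.DataFrame, schema: list[VariableSpec],
                       config: GeneratorConfig,
                       seed: int | np.random.Generator | None = None
                       ) -> pd.DataFrame:
    """Blank out cells, marking some categorical blanks with special codes.

    A ``missing_row_fraction`` share of rows receives >20% missing schema
    cells (so the downstream row filter has work to do); the remaining rows
    receive sparse cell-level missingness at ``missing_cell_rate``.  A
    ``special_code_share`` of categorical missing cells is written as an
    integer special code (e.g. -1 / -3) instead of NaN.
    """
    if seed is None:
        seed = config.seed + 1
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    out = table.copy()
    cols = _schema_cols(out, schema)
    cat_cols = {s.name for s in schema if not s.is_continuous}
    codes = [c for c, action in config.special_code_map.items()
             if action == "missing"]
    n, p = len(out), len(cols)
    if p == 0 or n == 0:
        return out

    for c in cols:
        if out[c].dtype != object and c in cat_cols:
            out[c] = out[c].astype(object)
        elif out[c].dtype != float and c not in cat_cols:
            out[c] = out[c].astype(float)

    heavy_rows = rng.choice(n, size=int(round(config.missing_row_fraction * n)),
                            replace=False)
    heavy = np.zeros(n, dtype=bool)
    heavy[heavy_rows] = True

    # heavy rows: strictly more than 20% of schema cells missing
    n_heavy_cells = int(np.floor(0.2 * p)) + 1
    for i in np.flatnonzero(heavy):
        hit = rng.choice(p, size=min(max(n_heavy_cells, int(0.3 * p)), p),
                         replace=False)
        for j in hit:
            c = cols[j]
            use_code = (c in cat_cols and codes
                        and rng.uniform() < config.special_code_share)
            out.iat[i, out.columns.get_loc(c)] = (
                int(rng.choice(codes)) if use_code else np.nan)

    # light rows: sparse cell-level missingness
    if config.missing_cell_rate > 0:
        light = ~heavy
        mask = rng.uniform(size=(n, p)) < config.missing_cell_rate
        mask[heavy, :] = False
        for j, c in enumerate(cols):
            rows = np.flatnonzero(mask[:, j] & light)
            for i in rows:
                use_code = (c in cat_cols and codes
                            and rng.uniform() < config.special_code_share)
                out.iat[i, out.columns.get_loc(c)] = (
                    int(rng.choice(codes)) if use_code else np.nan)
    return out


def inject_outliers(table: pd.DataFrame, schema: list[VariableSpec],
                    config: GeneratorConfig,
                    seed: int | np.random.Generator | None = None
                    ) -> tuple[pd.DataFrame, np.ndarray]:
    """Corrupt a fraction of rows into multivariate outliers; return ground truth.

    Selected rows become structurally inconsistent behavioral profiles:
    their categorical fields are regenerated from latent factors placed on a
    ring 3.2–5 within-component (Mahalanobis) standard deviations away from
    the row's parent population component — an improbable joint profile
    along the population's own dependence structure — and every continuous
    field is additionally shifted by roughly ``outlier_scale`` marginal
    standard deviations, signed along the row's latent deviation with a
    wide magnitude jitter.  The random ring angle and magnitude continuum
    keep corrupted rows mutually dissimilar, so they scatter at the margins
    of the legitimate clusters instead of forming a coherent cluster of
    their own.  With ``latent_correlation == 0`` (independent covariates),
    only the continuous shifts plus random categorical flips are applied.
    Returns the corrupted table and the positional indices of the altered
    rows.
    """
    if seed is None:
        seed = config.seed + 2
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    out = table.copy()
    n = len(out)
    k = int(round(config.outlier_fraction * n))
    idx = np.sort(rng.choice(n, size=k, replace=False)) if k else np.array([], int)
    if k == 0:
        return out, idx

    sds = {s.name: float(np.nanstd(pd.to_numeric(out[s.name], errors="coerce")))
           for s in schema if s.is_continuous and s.name in out.columns}

    if config.latent_correlation > 0:
        fmap = DEFAULT_FACTOR_MAP
        n_factors = 1 + max((f for f, _ in fmap.values()), default=0)
        comp = rng.choice([-1.0, 1.0], size=k)          # parent component
        radius = rng.uniform(3.2, 5.0, size=k)          # Mahalanobis-tail radii
        theta = rng.uniform(0.0, 2.0 * np.pi, size=k)
        u = np.zeros((k, max(n_factors, 2)))
        u[:, 0] = (comp * BIMODAL_DELTA
                   + radius * np.cos(theta) * BIMODAL_SIGMA)
        u[:, 1] = radius * np.sin(theta)
        z_by_var = {}
        for spec in schema:
            f, load = fmap.get(spec.name, (0, 0.0))
            rho = float(np.clip(config.latent_correlation * load, -0.99, 0.99))
            # reduced residual noise keeps corrupted rows on the extreme shell
            z_by_var[spec.name] = (rho * u[:, f] + np.sqrt(1.0 - rho ** 2)
                                   * 0.4 * rng.standard_normal(k))
        vals = _values_from_latent(schema, z_by_var,
                                   config.latent_correlation, fmap)
        for spec in schema:
            if spec.name not in out.columns:
                continue
            col = out.columns.get_loc(spec.name)
            v = vals[spec.name]
            if spec.is_continuous:
                # shift direction follows the row's latent deviation so the
                # continuous extreme reinforces the deviant profile; a wide
                # magnitude jitter keeps corrupted rows a radial continuum
                f, _ = fmap.get(spec.name, (0, 0.0))
                sgn = np.sign(np.cos(theta)) if f == 0 else np.sign(np.sin(theta))
                sgn = np.where(sgn == 0, 1.0, sgn)
                mag = config.outlier_scale * sds[spec.name] * rng.uniform(0.5, 1.5, k)
                v = np.asarray(v, float) + sgn * mag
            for j, i in enumerate(idx):
                out.iat[i, col] = v[j]
        return out, idx

    # independent-covariate fallback: continuous shifts + random flips
    for spec in schema:
        if spec.name not in out.columns:
            continue
        col = out.columns.get_loc(spec.name)
        if spec.is_continuous:
            signs = rng.choice([-1.0, 1.0], size=k)
            mags = config.outlier_scale * sds[spec.name] * rng.uniform(0.8, 1.4, k)
            for i, sgn, m in zip(idx, signs, mags):
                out.iat[i, col] = float(out.iat[i, col]) + sgn * m
        else:
            for i in idx:
                if rng.uniform() < 0.5:
                    continue
                current = out.iat[i, col]
                others = [lev for lev in spec.levels if lev != current]
                out.iat[i, col] = others[rng.integers(len(others))]
    return out, idx
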