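import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test

from behavnet.reference import (PROFILE_HIGH_RISK, PROFILE_PROTECTIVE,
                                REFERENCE_BETAS, REFERENCE_STRATA_RANGES)
from behavnet.survival import (NOT_REACHED, RiskStratification, assign_stratum,
                               cross_validate_cindex, derive_strata,
                               fit_multivariate_cox, hazard_table, hr_percent,
                               km_validation, low_variance_filter, risk_score,
                               risk_scores, univariate_screen, vif_filter)
from behavnet.survival import test_proportional_hazards as ph_diagnostics

from conftest import survival_frame


class TestUnivariateScreen:
    def test_strong_effect_retained_noise_not_forced(self):
        df = survival_frame({"strong": 0.8, "noise": 0.0}, n=3_000, seed=0,
                            censor=15.0)
        kept = univariate_screen(df, ["strong", "noise"], alpha=0.05)
        assert "strong" in kept

    def test_alpha_one_retains_everything(self):
        df = survival_frame({"a": 0.3, "b": 0.0}, n=500, seed=1, censor=15.0)
        assert univariate_screen(df, ["a", "b"], alpha=1.0) == ["a", "b"]


class TestVif:
    def test_near_collinear_pair_loses_one(self):
        rng = np.random.default_rng(2)
        x1 = rng.normal(size=500)
        design = pd.DataFrame({"x1": x1, "x2": 2 * x1 + 1e-3 * rng.normal(size=500),
                               "x3": rng.normal(size=500)})
        kept = vif_filter(design, threshold=10)
        assert "x3" in kept
        assert len({"x1", "x2"} & set(kept)) == 1

    def test_orthogonal_columns_all_retained(self):
        rng = np.random.default_rng(3)
        design = pd.DataFrame(rng.normal(size=(500, 4)),
                              columns=list("abcd"))
        assert vif_filter(design, threshold=10) == list("abcd")

    def test_r2_095_column_removed(self):
        # VIF = 1/(1-0.95) = 20 > 10
        rng = np.random.default_rng(4)
        z = rng.normal(size=2_000)
        y = np.sqrt(0.95) * z + np.sqrt(0.05) * rng.normal(size=2_000)
        design = pd.DataFrame({"z": z, "y": y, "w": rng.normal(size=2_000)})
        kept = vif_filter(design, threshold=10)
        assert len(kept) == 2 and "w" in kept

    def test_single_column_passthrough(self):
        design = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        assert vif_filter(design) == ["a"]


class TestLowVariance:
    def test_all_zero_indicator_dropped(self):
        design = pd.DataFrame({"zero": [0.0] * 100, "ok": [0, 1] * 50})
        events = np.array([0] * 50 + [1] * 50)   # ok balanced in both strata
        kept = low_variance_filter(design, events, 0.05)
        assert kept == ["ok"]

    def test_balanced_indicator_kept(self):
        design = pd.DataFrame({"b": [0, 1] * 50})
        events = np.array([0] * 50 + [1] * 50)
        assert low_variance_filter(design, events, 0.05) == ["b"]

    def test_matches_brute_force_stratum_scan(self):
        rng = np.random.default_rng(5)
        design = pd.DataFrame({f"c{i}": rng.binomial(1, p, 300).astype(float)
                               for i, p in enumerate([0.5, 0.02, 0.2, 0.005])})
        events = rng.integers(0, 2, 300)
        kept = low_variance_filter(design, events, min_level_freq=0.05)
        brute = []
        for c in design.columns:
            x = design[c].to_numpy()
            ok = True
            for m in (np.ones(300, bool), events == 1, events == 0):
                p1 = x[m].mean()
                if min(p1, 1 - p1) < 0.05:
                    ok = False
            if ok:
                brute.append(c)
        assert kept == brute


class TestMultivariateFit:
    def test_recovers_known_betas_within_ci(self):
        truth = {"a": 0.7, "b": -0.5, "c_u": 1.0}
        df = survival_frame(truth, n=4_000, seed=6, censor=15.0)
        fit = fit_multivariate_cox(df, list(truth), l2=0.0, stepwise=False)
        for t in fit.terms:
            lo, hi = np.log(t["ci_low"]), np.log(t["ci_high"])
            assert lo <= truth[t["name"]] <= hi

    def test_ridge_shrinks_coefficients_monotonically(self):
        df = survival_frame({"a": 1.0}, n=2_000, seed=7, censor=15.0)
        mags = []
        for l2 in (0.0, 1.0, 10.0):
            fit = fit_multivariate_cox(df, ["a"], l2=l2, stepwise=False)
            mags.append(abs(fit.betas["a"]))
        assert mags[0] > mags[1] > mags[2]

    def test_stepwise_removes_null_term_and_refits(self):
        df = survival_frame({"a": 0.8, "noise": 0.0}, n=3_000, seed=8,
                            censor=15.0)
        fit = fit_multivariate_cox(df, ["a", "noise"], l2=0.0, alpha=0.05)
        assert "a" in fit.term_names
        # reported estimates come from the final refit
        refit = fit_multivariate_cox(df, fit.term_names, l2=0.0,
                                     stepwise=False)
        for t1, t2 in zip(fit.terms, refit.terms):
            assert t1["beta"] == pytest.approx(t2["beta"], abs=1e-8)

    def test_no_candidates_raises(self):
        df = survival_frame({"a": 0.0}, n=50, seed=9, censor=15.0)
        with pytest.raises(ValueError):
            fit_multivariate_cox(df, [], l2=0.0)


def _decaying_effect_frame(n, seed, beta0=1.2, change=3.0):
    """Piecewise-exponential times: effect beta0 before `change`, 0 after."""
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, n).astype(float)
    lam0 = 1.0 / 10.0
    t1 = rng.exponential(1.0 / (lam0 * np.exp(beta0 * x)))
    t2 = change + rng.exponential(1.0 / lam0, size=n)
    T = np.where(t1 < change, t1, t2)
    censor = 15.0
    return pd.DataFrame({"x": x, "follow_up_years": np.minimum(T, censor),
                         "event": (T <= censor).astype(int)})


class TestProportionalHazards:
    def test_constant_effect_rarely_flagged(self):
        df = survival_frame({"a": 0.6}, n=2_000, seed=10, censor=15.0)
        fit = fit_multivariate_cox(df, ["a"], l2=0.0, stepwise=False)
        flags, refit = ph_diagnostics(fit, df, alpha=0.01)
        assert flags["flagged"] == []
        assert refit.time_interactions == []

    def test_decaying_effect_flagged_with_interaction_term(self):
        df = _decaying_effect_frame(4_000, seed=11)
        fit = fit_multivariate_cox(df, ["x"], l2=0.0, stepwise=False)
        flags, refit = ph_diagnostics(fit, df, alpha=0.05)
        assert "x" in flags["flagged"]
        assert "x__x_time" in refit.term_names
        inter = next(t for t in refit.terms if t["name"] == "x__x_time")
        assert inter["beta"] < 0    # effect decays in time


class TestCrossValidation:
    def test_strong_signal_high_concordance(self):
        df = survival_frame({"s_u": 30.0}, n=2_000, seed=12, censor=None)
        cv = cross_validate_cindex(df, ["s_u"], l2=0.0, folds=5, seed=0)
        assert cv["mean"] >= 0.95

    def test_pure_noise_near_half(self):
        df = survival_frame({"n_u": 0.0}, n=2_000, seed=13, censor=None)
        cv = cross_validate_cindex(df, ["n_u"], l2=0.0, folds=5, seed=0)
        assert abs(cv["mean"] - 0.5) < 0.03

    def test_seeded_folds_reproducible(self):
        df = survival_frame({"a": 0.5}, n=500, seed=14, censor=15.0)
        a = cross_validate_cindex(df, ["a"], folds=5, seed=3)
        b = cross_validate_cindex(df, ["a"], folds=5, seed=3)
        assert a == b

    def test_fold_without_events_raises(self):
        df = survival_frame({"a": 0.0}, n=40, seed=15, censor=15.0)
        df["event"] = 0
        df.loc[0, "event"] = 1
        with pytest.raises(ValueError, match="fold"):
            cross_validate_cindex(df, ["a"], folds=10, seed=0)


class TestHazardTable:
    def test_printed_arithmetic_tobacco_row(self):
        from behavnet.survival import CoxFitResult
        fit = CoxFitResult(terms=[{"name": "current_tobacco_smoking",
                                   "beta": 0.29, "se": 0.08,
                                   "hr": np.exp(0.29), "hr_pct": 0.0,
                                   "p": 1e-4, "ci_low": 1.14, "ci_high": 1.58}])
        row = hazard_table(fit).iloc[0]
        assert row["hr"] == 1.34
        assert row["hr_pct"] == 34.00

    def test_zero_beta_row(self):
        from behavnet.survival import CoxFitResult
        fit = CoxFitResult(terms=[{"name": "t", "beta": 0.0, "se": 1.0,
                                   "hr": 1.0, "hr_pct": 0.0, "p": 1.0,
                                   "ci_low": 0.9, "ci_high": 1.1}])
        row = hazard_table(fit).iloc[0]
        assert row["hr"] == 1.00 and row["hr_pct"] == 0.00

    def test_hr_percent_from_printed_hr(self):
        assert hr_percent(0.57) == -43.00
        assert hr_percent(1.34) == 34.00

    def test_table_round_trips_through_csv(self, tmp_path):
        from behavnet.survival import CoxFitResult
        fit = CoxFitResult(terms=[{"name": "a", "beta": 0.123, "se": 0.05,
                                   "hr": np.exp(0.123), "hr_pct": 0.0,
                                   "p": 0.01, "ci_low": 1.02, "ci_high": 1.25}])
        tab = hazard_table(fit)
        path = tmp_path / "t.csv"
        tab.to_csv(path, index=False)
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(back, tab)


class TestRiskScore:
    def test_worked_protective_profile(self):
        assert risk_score(REFERENCE_BETAS, PROFILE_PROTECTIVE) == pytest.approx(-0.55)

    def test_worked_high_risk_profile(self):
        assert risk_score(REFERENCE_BETAS, PROFILE_HIGH_RISK) == pytest.approx(0.91)

    def test_all_reference_row_scores_zero(self):
        assert risk_score(REFERENCE_BETAS, {}) == 0.0

    def test_unknown_term_raises(self):
        with pytest.raises(KeyError):
            risk_score(REFERENCE_BETAS, {"not_a_term": 1.0})

    def test_vectorized_matches_scalar(self):
        design = pd.DataFrame(0.0, index=[0, 1],
                              columns=list(REFERENCE_BETAS))
        for k, v in PROFILE_HIGH_RISK.items():
            design.loc[1, k] = v
        s = risk_scores(REFERENCE_BETAS, design)
        assert s[0] == 0.0
        assert s[1] == pytest.approx(0.91)


class TestStrata:
    def test_separated_clusters_recover_cutpoints(self):
        rng = np.random.default_rng(16)
        centers = [-1.5, -0.5, 0.5, 1.5, 2.5]
        rates = [0.05, 0.2, 0.4, 0.6, 0.9]
        scores, events = [], []
        for c, r in zip(centers, rates):
            s = rng.normal(c, 0.1, 400)
            scores.append(s)
            events.append(rng.binomial(1, r, 400))
        scores, events = np.concatenate(scores), np.concatenate(events)
        strat = derive_strata(scores, events, seed=0)
        assert len(strat.cutpoints) == 4
        for cut, lo, hi in zip(strat.cutpoints, centers[:-1], centers[1:]):
            assert lo < cut < hi

    def test_two_leaves_give_one_cutpoint(self):
        rng = np.random.default_rng(17)
        s = rng.normal(size=500)
        e = (s > 0).astype(int)
        strat = derive_strata(s, e, n_leaves=2, seed=0)
        assert len(strat.cutpoints) == 1

    def test_frozen_thresholds_are_deterministic(self):
        rng = np.random.default_rng(18)
        s = rng.normal(size=500)
        e = rng.binomial(1, 1 / (1 + np.exp(-2 * s)))
        strat = derive_strata(s, e, seed=1)
        l1 = assign_stratum(s, strat)
        l2 = assign_stratum(s, strat)
        assert (l1 == l2).all()

    def test_too_few_distinct_scores_raise(self):
        with pytest.raises(ValueError, match="distinct"):
            derive_strata(np.array([1.0, 1.0, 2.0, 2.0]),
                          np.array([0, 0, 1, 1]), n_leaves=5)


@pytest.fixture(scope="module")
def published():
    return RiskStratification.from_ranges(REFERENCE_STRATA_RANGES)


class TestAssignStratum:

    def test_worked_examples_map_to_published_strata(self, published):
        assert assign_stratum(-0.55, published) == "very_low"
        assert assign_stratum(0.91, published) == "high"

    def test_gap_midpoint_goes_to_upper_stratum(self, published):
        assert assign_stratum(0.405, published) == "moderate"

    def test_out_of_span_clamps_with_warning(self, published):
        with pytest.warns(UserWarning, match="clamped"):
            assert assign_stratum(-5.0, published) == "very_low"
        with pytest.warns(UserWarning, match="clamped"):
            assert assign_stratum(9.0, published) == "very_high"


class TestKMValidation:
    def test_uncensored_km_equals_empirical_survival(self):
        rng = np.random.default_rng(19)
        t_a = rng.exponential(5.0, 300) + 1
        t_b = rng.exponential(1.0, 50) + 1
        df = pd.DataFrame({
            "follow_up_years": np.concatenate([t_a, t_b]),
            "event": 1,
        })
        labels = np.array(["a"] * 300 + ["b"] * 50)
        km = km_validation(df, labels)
        curve = km.curves["a"]
        # no censoring: S(t) = fraction of sample still event-free
        for _, row in curve.iloc[::37].iterrows():
            emp = (t_a > row["time"]).mean()
            assert row["survival"] == pytest.approx(emp, abs=1e-9)
        assert km.percentiles["a"]["p50"] == pytest.approx(
            np.percentile(t_a, 50), rel=0.02)

    def test_curves_monotone_from_one(self):
        rng = np.random.default_rng(20)
        df = pd.DataFrame({
            "follow_up_years": rng.exponential(5.0, 200) + 1,
            "event": rng.integers(0, 2, 200),
        })
        labels = np.array(["a", "b"] * 100)
        km = km_validation(df, labels)
        for c in km.curves.values():
            s = c["survival"].to_numpy()
            assert s[0] == 1.0
            assert (np.diff(s) <= 1e-12).all()

    def test_not_reached_sentinel(self):
        # stratum with almost no events never crosses the 25% threshold
        df = pd.DataFrame({
            "follow_up_years": np.r_[np.full(99, 17.0), [5.0],
                                     np.linspace(1, 10, 50)],
            "event": np.r_[np.zeros(99, int), [1], np.ones(50, int)],
        })
        labels = np.array(["low"] * 100 + ["high"] * 50)
        km = km_validation(df, labels)
        assert km.percentiles["low"]["p25"] == NOT_REACHED

    def test_identical_strata_logrank_null_calibration(self):
        rng = np.random.default_rng(21)
        pvals = []
        for _ in range(200):
            ta, tb = rng.exponential(5, 60), rng.exponential(5, 60)
            res = logrank_test(ta, tb, np.ones(60), np.ones(60))
            pvals.append(res.p_value)
        # p-values approximately uniform: mean near 0.5, spread over (0,1)
        assert abs(np.mean(pvals) - 0.5) < 0.1
        assert (np.array(pvals) < 0.05).mean() < 0.12

    def test_pairwise_tests_cover_all_pairs(self):
        rng = np.random.default_rng(22)
        df = pd.DataFrame({
            "follow_up_years": rng.exponential(5.0, 300) + 1,
            "event": 1,
        })
        labels = rng.choice(["a", "b", "c"], 300)
        km = km_validation(df, labels)
        assert len(km.pairwise_tests) == 3
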