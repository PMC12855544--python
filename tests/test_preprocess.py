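import numpy as np
import pandas as pd
import pytest

from behavnet.preprocess import (balance_downsample, detect_outliers,
                                 filter_missing_rows, impute,
                                 recode_special_values, standardize)
from behavnet.schema import VariableSpec

from conftest import binary_spec


def nominal_spec(name, levels, ref=None):
    return VariableSpec(name=name, scale="nominal", levels=levels,
                        reference_level=ref or levels[0])


class TestRecode:
    def test_missing_codes_become_nan(self):
        schema = [nominal_spec("a", ["x", "y"])]
        df = pd.DataFrame({"a": ["x", -1, "y", -3]})
        out = recode_special_values(df, schema, {-1: "missing", -3: "missing"})
        assert out["a"].isna().sum() == 2

    def test_none_of_above_maps_to_level(self):
        schema = [nominal_spec("salt", ["never", "sometimes"])]
        df = pd.DataFrame({"salt": [-7, "sometimes"]})
        out = recode_special_values(df, schema, {-7: {"salt": "never"}})
        assert out.loc[0, "salt"] == "never"

    def test_table_without_codes_unchanged(self):
        schema = [nominal_spec("a", ["x", "y"])]
        df = pd.DataFrame({"a": ["x", "y", "x"]})
        out = recode_special_values(df, schema, {-1: "missing"})
        pd.testing.assert_frame_equal(out, df)

    def test_exact_count_of_changed_cells(self):
        rng = np.random.default_rng(0)
        schema = [nominal_spec(f"c{i}", ["x", "y", "z"]) for i in range(5)]
        df = pd.DataFrame({f"c{i}": rng.choice(["x", "y", "z"], 100)
                           for i in range(5)}).astype(object)
        flat = [(r, c) for r in range(100) for c in range(5)]
        pick = rng.choice(len(flat), size=37, replace=False)
        for j in pick:
            r, c = flat[j]
            df.iat[r, c] = -1
        out = recode_special_values(df, schema, {-1: "missing"})
        assert int(out.isna().sum().sum()) == 37

    def test_code_colliding_with_level_raises(self):
        schema = [VariableSpec(name="a", scale="ordinal", levels=[-1, 0, 1],
                               reference_level=0)]
        df = pd.DataFrame({"a": [-1, 0]})
        with pytest.raises(ValueError, match="collides"):
            recode_special_values(df, schema, {-1: "missing"})


class TestRowFilter:
    @pytest.fixture()
    def wide(self):
        schema = [binary_spec(f"b{i}") for i in range(20)]
        df = pd.DataFrame(np.ones((3, 20), dtype=float),
                          columns=[f"b{i}" for i in range(20)])
        return schema, df

    def test_strictly_over_threshold_dropped(self, wide):
        schema, df = wide
        df.iloc[0, :5] = np.nan     # 25% missing -> drop
        df.iloc[1, :4] = np.nan     # exactly 20% -> keep
        kept, removed = filter_missing_rows(df, schema, 0.20)
        assert removed == 1
        assert len(kept) == 2

    def test_removed_count_matches_brute_force(self):
        rng = np.random.default_rng(1)
        schema = [binary_spec(f"b{i}") for i in range(10)]
        df = pd.DataFrame(rng.integers(0, 2, (200, 10)).astype(float),
                          columns=[f"b{i}" for i in range(10)])
        mask = rng.uniform(size=df.shape) < 0.15
        df = df.mask(mask)
        kept, removed = filter_missing_rows(df, schema, 0.20)
        brute = sum(1 for _, row in df.iterrows()
                    if row.isna().mean() > 0.20)
        assert removed == brute
        assert len(kept) + removed == 200

    def test_share_denominator_excludes_non_schema_columns(self, wide):
        schema, df = wide
        df["event"] = np.nan      # outcome column fully missing, must not count
        kept, removed = filter_missing_rows(df, schema, 0.20)
        assert removed == 0


class TestImpute:
    def test_binary_least_frequent(self):
        spec = binary_spec("b")
        df = pd.DataFrame({"b": [1, 1, 1, 0, np.nan]})
        assert impute(df, [spec]).loc[4, "b"] == 0

    def test_binary_tie_imputes_zero(self):
        spec = binary_spec("b")
        df = pd.DataFrame({"b": [1, 0, 1, 0, np.nan]})
        assert impute(df, [spec]).loc[4, "b"] == 0

    def test_continuous_mean(self):
        spec = VariableSpec(name="c", scale="continuous",
                            gen_params={"range": [0, 10]})
        df = pd.DataFrame({"c": [2.0, 4.0, np.nan]})
        assert impute(df, [spec]).loc[2, "c"] == 3.0

    def test_nominal_mode(self):
        spec = nominal_spec("n", ["a", "b"])
        df = pd.DataFrame({"n": ["a", "a", "b", np.nan]})
        assert impute(df, [spec]).loc[3, "n"] == "a"

    def test_never_invents_unseen_levels(self):
        spec = nominal_spec("n", ["a", "b", "c"])
        df = pd.DataFrame({"n": ["a", "b", np.nan, np.nan, "a"]})
        out = impute(df, [spec])
        assert set(out["n"]) <= {"a", "b"}

    def test_entirely_missing_column_raises(self):
        spec = binary_spec("b")
        df = pd.DataFrame({"b": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="entirely missing"):
            impute(df, [spec])


class TestStandardize:
    def test_mean_zero_sd_one(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        z = standardize(df)
        assert abs(z["a"].mean()) < 1e-9
        assert abs(z["a"].std(ddof=0) - 1.0) < 1e-9

    def test_constant_column_becomes_zeros(self):
        df = pd.DataFrame({"a": [5.0, 5.0, 5.0], "b": [1.0, 2.0, 3.0]})
        z = standardize(df)
        assert (z["a"] == 0.0).all()

    def test_round_trip_recovers_input(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"a": rng.normal(3, 2, 50)})
        z = standardize(df)
        back = z["a"] * df["a"].std(ddof=0) + df["a"].mean()
        assert np.allclose(back, df["a"], atol=1e-9)


@pytest.fixture(scope="module")
def blobs():
    rng = np.random.default_rng(3)
    a = rng.normal([0, 0, 0], 0.5, size=(250, 3))
    b = rng.normal([8, 8, 8], 0.5, size=(250, 3))
    return np.vstack([a, b])


class TestDetectOutliers:

    def test_two_blobs_select_k2(self, blobs):
        rep = detect_outliers(standardize(pd.DataFrame(blobs)),
                              method="pca", seed=0)
        assert rep.k_selected == 2

    def test_flagged_share_is_five_percent_per_cluster(self, blobs):
        rep = detect_outliers(standardize(pd.DataFrame(blobs)),
                              method="pca", seed=0)
        for c in np.unique(rep.cluster_labels):
            size = int((rep.cluster_labels == c).sum())
            flagged = np.isin(np.flatnonzero(rep.cluster_labels == c),
                              rep.flagged_rows).sum()
            assert abs(flagged - 0.05 * size) <= 1

    def test_k_selection_is_argmax_of_silhouette(self, blobs):
        rep = detect_outliers(standardize(pd.DataFrame(blobs)),
                              method="pca", seed=0)
        assert rep.k_selected == max(rep.silhouette_by_k,
                                     key=lambda k: (rep.silhouette_by_k[k], -k))

    def test_row_order_invariance(self, blobs):
        z = standardize(pd.DataFrame(blobs))
        rep1 = detect_outliers(z, method="pca", seed=0)
        perm = np.random.default_rng(4).permutation(len(z))
        rep2 = detect_outliers(z.iloc[perm].reset_index(drop=True),
                               method="pca", seed=0)
        back = set(perm[rep2.flagged_rows])
        assert back == set(rep1.flagged_rows.tolist())

    def test_tsne_smoke_and_perplexity_guard(self, blobs):
        with pytest.raises(ValueError, match="perplexity"):
            detect_outliers(blobs[:100], method="tsne", perplexity=40)
        rep = detect_outliers(standardize(pd.DataFrame(blobs)), method="tsne",
                              perplexity=30, n_iter=300, seed=0)
        assert rep.k_selected == 2
        assert len(rep.flagged_rows) > 0

    def test_global_percentile_variant(self, blobs):
        rep = detect_outliers(standardize(pd.DataFrame(blobs)), method="pca",
                              per_cluster=False, seed=0)
        assert abs(len(rep.flagged_rows) - 0.05 * len(blobs)) <= 2


class TestBalance:
    def test_downsamples_healthy_to_t2dm_size(self):
        h = pd.DataFrame({"x": range(100)})
        t = pd.DataFrame({"x": range(40)})
        hs, ts = balance_downsample(h, t, seed=0)
        assert len(hs) == 40 and len(ts) == 40

    def test_equal_sizes_unchanged(self):
        h = pd.DataFrame({"x": range(10)})
        t = pd.DataFrame({"x": range(10)})
        hs, _ = balance_downsample(h, t, seed=0)
        pd.testing.assert_frame_equal(hs, h)

    def test_wrong_direction_raises(self):
        with pytest.raises(ValueError, match="direction"):
            balance_downsample(pd.DataFrame({"x": [1]}),
                               pd.DataFrame({"x": [1, 2]}), seed=0)

    def test_subsample_preserves_means(self):
        rng = np.random.default_rng(5)
        h = pd.DataFrame({"x": rng.normal(size=20_000)})
        t = pd.DataFrame({"x": rng.normal(size=10_000)})
        hs, _ = balance_downsample(h, t, seed=1)
        se = h["x"].std() / np.sqrt(len(hs))
        assert abs(hs["x"].mean() - h["x"].mean()) < 3 * se
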