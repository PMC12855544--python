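import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from behavnet.influence import InfluenceEstimate, InfluenceMatrix
from behavnet.network import (EdgeRule, METRICS, RoleRules, build_network,
                              centrality_deltas, centrality_profile,
                              classify_roles, vector_shift)


def matrix_from_dict(values, variables=None, tier="highly_stable"):
    ests = {(i, t): InfluenceEstimate(input=i, target=t, median_weight=v,
                                      pct_positive=80, pct_negative=20,
                                      tier=tier)
            for (i, t), v in values.items()}
    if variables is None:
        variables = sorted({k[0] for k in values} | {k[1] for k in values})
    return InfluenceMatrix(variables=variables, estimates=ests)


def random_digraph(seed, n=None):
    rng = np.random.default_rng(seed)
    n = n or int(rng.integers(4, 30))
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for u, v in itertools.permutations(range(n), 2):
        if rng.uniform() < 0.2:
            w = float(rng.uniform(0.1, 2.0))
            g.add_edge(u, v, weight=w, distance=1.0 / w)
    return g


class TestBuildNetwork:
    def test_single_positive_entry_gives_one_edge(self):
        m = matrix_from_dict({("a", "b"): 0.5, ("b", "a"): -0.3})
        g = build_network(m)
        assert g.number_of_edges() == 1
        assert g["a"]["b"]["weight"] == 0.5

    def test_all_negative_matrix_gives_empty_graph(self):
        m = matrix_from_dict({("a", "b"): -0.5, ("b", "a"): -0.3})
        with pytest.warns(UserWarning, match="no edges"):
            g = build_network(m)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 2

    def test_edge_count_non_increasing_in_threshold(self):
        rng = np.random.default_rng(1)
        vals = {(f"n{i}", f"n{j}"): float(rng.normal())
                for i in range(6) for j in range(6) if i != j}
        m = matrix_from_dict(vals)
        counts = [build_network(m, EdgeRule(threshold=t)).number_of_edges()
                  for t in (0.0, 0.3, 0.6, 1.0)]
        assert counts == sorted(counts, reverse=True)

    def test_stability_gate_drops_unstable_edges(self):
        ests = {
            ("a", "b"): InfluenceEstimate("a", "b", 0.5, 80, 20, "highly_stable"),
            ("b", "a"): InfluenceEstimate("b", "a", 0.5, 52, 48, "low_stability"),
        }
        m = InfluenceMatrix(variables=["a", "b"], estimates=ests)
        g = build_network(m, EdgeRule(min_tier="moderately_stable"))
        assert g.number_of_edges() == 1


class TestCentrality:
    def test_three_cycle_pagerank_uniform(self):
        g = nx.DiGraph([("a", "b"), ("b", "c"), ("c", "a")])
        nx.set_edge_attributes(g, 1.0, "weight")
        nx.set_edge_attributes(g, 1.0, "distance")
        prof = centrality_profile(g)
        assert np.allclose(prof["pagerank"], 1 / 3)

    def test_star_degree_normalization(self):
        g = nx.DiGraph()
        g.add_edges_from(("hub", f"leaf{i}", {"weight": 1.0, "distance": 1.0})
                         for i in range(24))
        prof = centrality_profile(g)
        assert prof.loc["hub", "out_degree"] == 1.0
        assert prof.loc["leaf0", "in_degree"] == pytest.approx(1 / 24)

    def test_betweenness_matches_brute_force_enumeration(self):
        # exhaustive shortest-path counting on small unweighted digraphs
        for seed in range(5):
            g = random_digraph(seed, n=6)
            prof = centrality_profile(g, weighted_paths=False)
            n = g.number_of_nodes()
            brute = {v: 0.0 for v in g}
            for s, t in itertools.permutations(g.nodes, 2):
                try:
                    paths = list(nx.all_shortest_paths(g, s, t))
                except nx.NetworkXNoPath:
                    continue
                for v in g:
                    if v in (s, t):
                        continue
                    through = sum(1 for p in paths if v in p[1:-1])
                    brute[v] += through / len(paths)
            scale = 1.0 / ((n - 1) * (n - 2))
            for v in g:
                assert prof.loc[v, "betweenness"] == pytest.approx(
                    brute[v] * scale, abs=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_normalization_invariants_on_random_graphs(self, seed):
        g = random_digraph(seed)
        if g.number_of_edges() == 0:
            pytest.skip("degenerate draw")
        prof = centrality_profile(g)
        assert prof["pagerank"].sum() == pytest.approx(1.0, abs=1e-9)
        assert prof["in_degree"].between(0, 1).all()
        assert prof["out_degree"].between(0, 1).all()
        assert prof["eigenvector"].max() == pytest.approx(1.0)
        assert (prof["betweenness"] >= 0).all()


class TestDeltas:
    def _profiles(self):
        idx = ["tobacco", "muesli"]
        healthy = pd.DataFrame({
            "in_degree": [0.44, 0.48], "out_degree": [0.28, 0.60],
            "eigenvector": [0.43, 0.07], "betweenness": [0.10, 0.21],
            "pagerank": [0.04, 0.05]}, index=idx)
        t2dm = pd.DataFrame({
            "in_degree": [0.72, 0.20], "out_degree": [0.52, 0.36],
            "eigenvector": [0.87, 0.01], "betweenness": [0.15, 0.10],
            "pagerank": [0.07, 0.03]}, index=idx)
        return healthy, t2dm

    def test_reported_shift_arithmetic(self):
        healthy, t2dm = self._profiles()
        d = centrality_deltas(healthy, t2dm)
        assert d.loc["tobacco", "delta_eigenvector"] == pytest.approx(0.44)
        assert d.loc["tobacco", "delta_in_degree"] == pytest.approx(0.28)
        assert d.loc["muesli", "delta_in_degree"] == pytest.approx(-0.28)

    def test_identical_profiles_zero_delta(self):
        healthy, _ = self._profiles()
        d = centrality_deltas(healthy, healthy)
        for m in METRICS:
            assert (d[f"delta_{m}"] == 0).all()

    def test_swapped_arguments_negate(self):
        healthy, t2dm = self._profiles()
        d1 = centrality_deltas(healthy, t2dm)
        d2 = centrality_deltas(t2dm, healthy)
        for m in METRICS:
            assert np.allclose(d1[f"delta_{m}"], -d2[f"delta_{m}"])

    def test_node_mismatch_raises(self):
        healthy, t2dm = self._profiles()
        with pytest.raises(ValueError, match="node sets"):
            centrality_deltas(healthy, t2dm.drop("muesli"))


class TestVectorShift:
    def _profiles(self):
        healthy = pd.DataFrame({"eigenvector": [0.1, 0.4],
                                "betweenness": [0.2, 0.1],
                                "in_degree": [0, 0], "out_degree": [0, 0],
                                "pagerank": [0.5, 0.5]}, index=["a", "b"])
        t2dm = healthy.copy()
        t2dm.loc["a", ["eigenvector", "betweenness"]] = [0.4, 0.6]
        return healthy, t2dm

    def test_unchanged_node_has_zero_arrow(self):
        h, t = self._profiles()
        shift = vector_shift(h, t)
        assert shift.loc["b", "magnitude"] == 0.0

    def test_three_four_five_magnitude(self):
        h, t = self._profiles()
        shift = vector_shift(h, t)   # delta = (0.3, 0.4)
        assert shift.loc["a", "magnitude"] == pytest.approx(0.5)

    def test_arrows_consistent_with_deltas(self):
        h, t = self._profiles()
        shift = vector_shift(h, t)
        d = centrality_deltas(h, t, ndigits=10)
        for v in shift.index:
            assert shift.loc[v, "tip_x"] - shift.loc[v, "base_x"] == \
                pytest.approx(d.loc[v, "delta_eigenvector"])

    def test_unknown_metric_raises(self):
        h, t = self._profiles()
        with pytest.raises(ValueError, match="unknown metric"):
            vector_shift(h, t, axes=("eigenvector", "bogus"))


class TestRoles:
    def _delta_table(self):
        return pd.DataFrame({
            "delta_eigenvector": [0.44, -0.07, -0.11, 0.0],
            "delta_in_degree": [0.28, -0.28, 0.20, 0.0],
            "delta_out_degree": [0.24, -0.24, 0.12, 0.0],
            "delta_betweenness": [0.05, -0.11, 0.0, 0.0],
        }, index=["tobacco", "muesli", "loneliness", "cheese_ref"])

    def _hazards(self):
        return pd.DataFrame({
            "term": ["tobacco", "muesli", "loneliness", "cheese_ref"],
            "hr": [1.34, 0.57, 1.14, 1.00],
            "p": [1e-4, 1e-4, 1e-4, 0.9],
        })

    def test_reported_category_examples(self):
        roles = classify_roles(self._delta_table(), self._hazards())
        assert roles.loc["tobacco", "category"] == "dual_priority"
        assert roles.loc["muesli", "category"] == "structural_stabilizer"
        assert roles.loc["loneliness", "category"] == "emergent_driver"
        assert roles.loc["cheese_ref", "category"] == "other"

    def test_classification_is_pure_function(self):
        a = classify_roles(self._delta_table(), self._hazards())
        b = classify_roles(self._delta_table(), self._hazards())
        pd.testing.assert_frame_equal(a, b)

    def test_unmapped_node_warns_and_classifies_other(self):
        hz = self._hazards().iloc[:2]
        with pytest.warns(UserWarning, match="no mapped hazard term"):
            roles = classify_roles(self._delta_table(), hz,
                                   node_map={"tobacco": "tobacco",
                                             "muesli": "muesli"})
        assert roles.loc["loneliness", "category"] == "other"

    def test_categorical_terms_map_to_parent_node(self):
        hz = pd.DataFrame({"term": ["cereal[muesli]"], "hr": [0.57],
                           "p": [1e-4]})
        deltas = self._delta_table().loc[["muesli"]]
        roles = classify_roles(deltas, hz,
                               node_map={"cereal[muesli]": "muesli"})
        assert roles.loc["muesli", "category"] == "structural_stabilizer"
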