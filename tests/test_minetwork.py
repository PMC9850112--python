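"""MI estimation, prior-calibrated thresholds, and network analytics."""
import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sgccanet.blocks import OmicsBlock
from sgccanet.exceptions import ThresholdError, ValidationError
from sgccanet.minetwork import (RegulatoryPrior, build_network, default_nbins,
                                discretize_equal_frequency, dpi_filter,
                                edge_type_for, functional_subgraph, group_logfc,
                                ks_unify_thresholds, mutual_information,
                                node_metrics, pairwise_mi, prior_edge_thresholds)

from oracles import exhaustive_betweenness, mi_from_pairs


def _block(arr, omic, feats, samples=None):
    arr = np.asarray(arr, dtype=float)
    samples = samples or [f"s{i}" for i in range(arr.shape[0])]
    return OmicsBlock(pd.DataFrame(arr, index=samples, columns=feats), omic)


class TestDiscretize:
    def test_nine_distinct_values_three_equal_bins(self):
        codes = discretize_equal_frequency(np.arange(9.0), 3)
        assert np.bincount(codes).tolist() == [3, 3, 3]
        assert (np.diff(codes) >= 0).all()

    def test_nbins_equal_n_one_point_per_bin(self):
        codes = discretize_equal_frequency(np.array([3.0, 1.0, 2.0, 4.0]), 4)
        assert sorted(codes) == [0, 1, 2, 3]

    def test_ties_split_by_stable_order(self):
        codes = discretize_equal_frequency(np.array([1.0, 1.0, 1.0, 2.0, 3.0, 4.0]), 2)
        assert codes.tolist() == [0, 0, 0, 1, 1, 1]

    def test_constant_vector_collapses_to_one_bin(self):
        codes = discretize_equal_frequency(np.ones(6), 2)
        assert (codes == 0).all()


class TestMutualInformation:
    def test_identity_on_balanced_distinct_data_is_log_nbins(self):
        x = np.arange(8.0)
        assert mutual_information(x, x, 2) == pytest.approx(math.log(2), abs=1e-12)
        assert mutual_information(x, x, 4) == pytest.approx(math.log(4), abs=1e-12)

    def test_diagonal_joint_table_from_four_samples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([10.0, 20.0, 30.0, 40.0])
        # joint table [[2,0],[0,2]] -> MI = ln 2
        assert mutual_information(x, y, 2) == pytest.approx(math.log(2), abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal(30), rng.standard_normal(30)
        assert mutual_information(x, y) == pytest.approx(mutual_information(y, x),
                                                         abs=1e-15)

    def test_matches_independent_counter_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            n = int(rng.integers(4, 51))
            nbins = int(rng.integers(2, min(6, n + 1)))
            x = rng.standard_normal(n)
            y = x * rng.choice([-1, 1]) + rng.standard_normal(n)
            cx = discretize_equal_frequency(x, nbins)
            cy = discretize_equal_frequency(y, nbins)
            got = mutual_information(x, y, nbins)
            assert got == pytest.approx(mi_from_pairs(cx.tolist(), cy.tolist()),
                                        abs=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValidationError):
            mutual_information(np.arange(5.0), np.arange(6.0), 2)


class TestPairwiseMI:
    def _blocks(self, n=12, n_cpg=2, n_tr=2, n_mir=1):
        rng = np.random.default_rng(2)
        return [
            _block(rng.random((n, n_cpg)), "cpg", [f"cg{i}" for i in range(n_cpg)]),
            _block(rng.random((n, n_tr)), "transcript", [f"T{i}" for i in range(n_tr)]),
            _block(rng.random((n, n_mir)), "mirna", [f"m{i}" for i in range(n_mir)]),
        ]

    def test_single_cpg_transcript_pair(self):
        blocks = self._blocks(n_cpg=1, n_tr=1, n_mir=1)
        out = pairwise_mi(blocks[:2])
        assert len(out) == 1 and out.edge_type[0] == "cpg-transcript"

    def test_cpg_cpg_pairs_never_scored(self):
        out = pairwise_mi(self._blocks(n_tr=0, n_mir=0)[:1])
        assert out.empty

    def test_combinatorial_counts_with_tf_flag(self):
        out = pairwise_mi(self._blocks(), tf_features={"T0"})
        counts = out.edge_type.value_counts().to_dict()
        assert counts == {"cpg-transcript": 4, "cpg-mirna": 2,
                          "mirna-transcript": 2, "tf_transcript-transcript": 1}

    def test_non_tf_transcript_pairs_excluded(self):
        out = pairwise_mi(self._blocks(), tf_features=set())
        assert "tf_transcript-transcript" not in set(out.edge_type)


class TestEdgeTyping:
    @pytest.mark.parametrize("a, ta, b, tb, expected", [
        ("cpg", False, "transcript", True, "cpg-transcript"),
        ("mirna", False, "cpg", False, "cpg-mirna"),
        ("transcript", False, "mirna", False, "mirna-transcript"),
        ("transcript", True, "transcript", False, "tf_transcript-transcript"),
        ("transcript", False, "transcript", False, None),
        ("cpg", False, "cpg", False, None),
        ("mirna", False, "mirna", False, None),
    ])
    def test_admissible_types(self, a, ta, b, tb, expected):
        assert edge_type_for(a, ta, b, tb) == expected


class TestPriorThresholds:
    def test_single_prior_edge_threshold_is_its_mi(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(40)
        blocks = [_block(x[:, None], "cpg", ["cg0"]),
                  _block((x + rng.standard_normal(40))[:, None], "transcript", ["T0"])]
        priors = RegulatoryPrior(pd.DataFrame(
            [("cg0", "T0", "cpg-transcript", True)],
            columns=["source", "target", "edge_type", "validated"]))
        th = prior_edge_thresholds(priors, blocks, nbins=3)
        expected = mutual_information(blocks[0].values[:, 0],
                                      blocks[1].values[:, 0], 3)
        assert th == {"cpg-transcript": pytest.approx(expected)}

    def test_even_count_median_is_mean_of_central_pair(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((40, 2))
        Y = rng.standard_normal((40, 2))
        blocks = [_block(X, "cpg", ["cg0", "cg1"]),
                  _block(Y, "transcript", ["T0", "T1"])]
        priors = RegulatoryPrior(pd.DataFrame(
            [("cg0", "T0", "cpg-transcript", True),
             ("cg1", "T1", "cpg-transcript", True)],
            columns=["source", "target", "edge_type", "validated"]))
        th = prior_edge_thresholds(priors, blocks, nbins=3)
        mis = [mutual_information(X[:, i], Y[:, i], 3) for i in range(2)]
        assert th["cpg-transcript"] == pytest.approx(np.mean(mis))

    def test_no_usable_priors_raises(self):
        rng = np.random.default_rng(5)
        blocks = [_block(rng.random((10, 1)), "cpg", ["cg0"])]
        priors = RegulatoryPrior(pd.DataFrame(
            [("cgX", "TX", "cpg-transcript", True)],
            columns=["source", "target", "edge_type", "validated"]))
        with pytest.raises(ThresholdError):
            prior_edge_thresholds(priors, blocks)


class TestKSUnification:
    def test_identical_distributions_unify_to_minimum_median(self):
        d = np.linspace(0, 1, 20)
        th, mode, ks = ks_unify_thresholds({"a": d, "b": d.copy()},
                                           {"a": 0.4, "b": 0.25})
        assert mode == "unified"
        assert th == {"a": 0.25, "b": 0.25}
        assert (ks["statistic"] == 0).all()

    def test_disjoint_distributions_stay_per_type(self):
        th, mode, _ = ks_unify_thresholds(
            {"a": np.linspace(0, 1, 30), "b": np.linspace(10, 11, 30)},
            {"a": 0.5, "b": 10.5})
        assert mode == "per-type"
        assert th == {"a": 0.5, "b": 10.5}

    def test_three_vs_three_exact_null(self):
        # D = 1; exact two-sample KS null: p = 2 * 3! * 3! / 6! = 0.1
        _, _, ks = ks_unify_thresholds({"a": np.array([1.0, 2.0, 3.0]),
                                        "b": np.array([4.0, 5.0, 6.0])},
                                       {"a": 2.0, "b": 5.0})
        row = ks.iloc[0]
        assert row["statistic"] == 1.0
        assert row["p"] == pytest.approx(0.1)


def _toy_pairs():
    return pd.DataFrame([
        ("cg0", "T0", "cpg-transcript", 0.9),
        ("cg0", "T1", "cpg-transcript", 0.2),
        ("cg0", "m0", "cpg-mirna", 0.5),
        ("cg1", "m0", "cpg-mirna", 0.4),
        ("m0", "T0", "mirna-transcript", 0.3),
        ("m0", "T1", "mirna-transcript", 0.6),
    ], columns=["source", "target", "edge_type", "mi"])


def _toy_meta():
    feats = ["cg0", "cg1", "T0", "T1", "m0"]
    omic = ["cpg", "cpg", "transcript", "transcript", "mirna"]
    return pd.DataFrame({"omic_type": omic, "is_tf": False},
                        index=pd.Index(feats, name="feature"))


class TestBuildNetwork:
    def test_hand_filtered_edge_list(self):
        th = {"cpg-transcript": 0.5, "cpg-mirna": 0.45, "mirna-transcript": 0.6}
        g = build_network(_toy_pairs(), th, _toy_meta())
        edges = {tuple(sorted(e)) for e in g.edges}
        assert edges == {("T0", "cg0"), ("cg0", "m0"), ("T1", "m0")}

    def test_threshold_above_max_gives_empty_network(self):
        th = {t: 2.0 for t in ("cpg-transcript", "cpg-mirna", "mirna-transcript")}
        g = build_network(_toy_pairs(), th, _toy_meta())
        assert g.number_of_edges() == 0

    def test_zero_thresholds_keep_all_pairs_and_ties_survive(self):
        th = {t: 0.0 for t in ("cpg-transcript", "cpg-mirna", "mirna-transcript")}
        g = build_network(_toy_pairs(), th, _toy_meta())
        assert g.number_of_edges() == 6
        # closed threshold: an edge exactly at its threshold survives
        th2 = {"cpg-transcript": 0.2, "cpg-mirna": 1.0, "mirna-transcript": 1.0}
        g2 = build_network(_toy_pairs(), th2, _toy_meta())
        assert ("cg0", "T1") in g2.edges or ("T1", "cg0") in g2.edges

    def test_raising_any_threshold_never_adds_edges(self):
        base = {"cpg-transcript": 0.3, "cpg-mirna": 0.3, "mirna-transcript": 0.3}
        g_lo = build_network(_toy_pairs(), base, _toy_meta())
        for t in base:
            higher = dict(base, **{t: 0.55})
            g_hi = build_network(_toy_pairs(), higher, _toy_meta())
            assert set(g_hi.edges) <= set(g_lo.edges)

    def test_functional_isolated_node_retained(self):
        th = {t: 2.0 for t in ("cpg-transcript", "cpg-mirna", "mirna-transcript")}
        g = build_network(_toy_pairs(), th, _toy_meta(), functional={"T0"})
        assert set(g.nodes) == {"T0"} and g.nodes["T0"]["functional"]


class TestDPI:
    def _triangle(self, ws):
        g = nx.Graph()
        for (u, v), w in zip([("a", "b"), ("b", "c"), ("a", "c")], ws):
            g.add_edge(u, v, mi=w, edge_type="cpg-transcript")
        return g

    def test_weakest_edge_of_triangle_removed(self):
        g = dpi_filter(self._triangle([3.0, 2.0, 1.0]), 0.0)
        assert set(map(tuple, map(sorted, g.edges))) == {("a", "b"), ("b", "c")}

    def test_no_triangles_unchanged(self):
        g = nx.Graph()
        g.add_edge("a", "b", mi=1.0)
        g.add_edge("b", "c", mi=2.0)
        assert set(dpi_filter(g, 0.0).edges) == set(g.edges)

    def test_tolerance_spares_near_ties(self):
        g = dpi_filter(self._triangle([3.0, 2.0, 1.9]), tolerance=0.1)
        assert g.number_of_edges() == 3

    def test_two_triangles_sharing_an_edge_hand_worked(self):
        # abc: ab=3, bc=2, ac=1 -> remove ac; bcd: bc=2, cd=5, bd=1.5 -> remove bd
        g = nx.Graph()
        for u, v, w in [("a", "b", 3.0), ("b", "c", 2.0), ("a", "c", 1.0),
                        ("c", "d", 5.0), ("b", "d", 1.5)]:
            g.add_edge(u, v, mi=w)
        out = dpi_filter(g, 0.0)
        assert set(map(tuple, map(sorted, out.edges))) == {("a", "b"), ("b", "c"),
                                                           ("c", "d")}


class TestFunctionalSubgraph:
    def _star(self):
        g = nx.Graph()
        for leaf in "bcde":
            g.add_edge("a", leaf, mi=1.0)
        g.add_edge("x", "y", mi=1.0)      # second component, no functional node
        return g

    def test_component_without_functional_node_removed(self):
        sub = functional_subgraph(self._star(), {"a"})
        assert set(sub.nodes) == {"a", "b", "c", "d", "e"}

    def test_all_nodes_functional_is_identity(self):
        g = self._star()
        sub = functional_subgraph(g, set(g.nodes))
        assert set(sub.nodes) == set(g.nodes) and set(sub.edges) == set(g.edges)

    def test_first_neighbors_of_center_vs_leaf(self):
        whole = functional_subgraph(self._star(), {"a"}, first_neighbors_only=True)
        assert set(whole.nodes) == {"a", "b", "c", "d", "e"}
        leaf = functional_subgraph(self._star(), {"b"}, first_neighbors_only=True)
        assert set(leaf.nodes) == {"a", "b"}

    def test_output_is_vertex_induced(self):
        g = self._star()
        g.add_edge("b", "c", mi=0.5)
        sub = functional_subgraph(g, {"b"}, first_neighbors_only=True)
        # induced on {a, b, c}: every edge among those nodes must be present,
        # including a-c which touches no functional node
        assert set(map(tuple, map(sorted, sub.edges))) == {("a", "b"), ("a", "c"),
                                                           ("b", "c")}


class TestNodeMetrics:
    def test_path_graph_center(self):
        g = nx.Graph([("a", "b"), ("b", "c")])
        m = node_metrics(g)
        assert m.loc["b", "degree"] == 2
        assert m.loc["b", "betweenness"] == pytest.approx(1.0)

    def test_complete_graph_all_zero_betweenness(self):
        g = nx.complete_graph(5)
        m = node_metrics(g)
        assert (m["betweenness"] == 0).all()
        assert (m["degree"] == 4).all()

    @pytest.mark.parametrize("edges", [
        [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("b", "d")],
        [("a", "b"), ("a", "c"), ("a", "d"), ("d", "e")],
    ])
    def test_five_node_toys_match_exhaustive_enumeration(self, edges):
        g = nx.Graph(edges)
        m = node_metrics(g)
        oracle = exhaustive_betweenness(g.nodes, edges)
        for v in g.nodes:
            assert m.loc[v, "betweenness"] == pytest.approx(oracle[v], abs=1e-12)


class TestGroupLogFC:
    def test_identical_groups_zero_logfc(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((4, 3))
        b = _block(np.vstack([X, X]), "transcript", ["f0", "f1", "f2"],
                   samples=[f"s{i}" for i in range(8)])
        out = group_logfc(b, [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)])
        assert np.allclose(out["logfc"], 0.0)

    def test_constant_shift_gives_unit_logfc(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((4, 2))
        b = _block(np.vstack([X + 1.0, X]), "transcript", ["f0", "f1"],
                   samples=[f"s{i}" for i in range(8)])
        out = group_logfc(b, [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)])
        assert np.allclose(out["logfc"], 1.0)

    def test_four_vs_four_matches_hand_welch(self):
        ga = np.array([1.0, 2.0, 3.0, 4.0])
        gb = np.array([2.0, 2.0, 2.0, 6.0])
        b = _block(np.concatenate([ga, gb])[:, None], "transcript", ["f0"],
                   samples=[f"s{i}" for i in range(8)])
        out = group_logfc(b, [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)])
        va, vb = ga.var(ddof=1) / 4, gb.var(ddof=1) / 4
        t = (ga.mean() - gb.mean()) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / 3 + vb ** 2 / 3)
        p = 2 * stats.t.sf(abs(t), df)
        assert out.loc["f0", "logfc"] == pytest.approx(ga.mean() - gb.mean())
        assert out.loc["f0", "p"] == pytest.approx(p, rel=1e-12)

    def test_degenerate_variance_flagged_with_p_one(self):
        b = _block(np.ones((6, 1)), "transcript", ["f0"],
                   samples=[f"s{i}" for i in range(6)])
        out = group_logfc(b, [f"s{i}" for i in range(3)], [f"s{i}" for i in range(3, 6)])
        assert out.loc["f0", "p"] == 1.0 and bool(out.loc["f0", "degenerate"])


class TestDataProcessingInequalitySanity:
    def test_chain_mi_ordering_at_n_500(self):
        rng = np.random.default_rng(8)
        n = 500
        c = rng.standard_normal(n)
        t = c + 0.5 * rng.standard_normal(n)
        m = t + 0.5 * rng.standard_normal(n)
        nbins = default_nbins(n)
        mi_ct = mutual_information(c, t, nbins)
        mi_tm = mutual_information(t, m, nbins)
        mi_cm = mutual_information(c, m, nbins)
        assert mi_cm <= min(mi_ct, mi_tm) + 0.05


class TestPlantedPriorRetention:
    def test_true_edges_beat_decoys(self, mi_dataset):
        from conftest import preprocess_blocks
        blocks = preprocess_blocks(mi_dataset)
        col = {f: b.values[:, i] for b in blocks for i, f in enumerate(b.feature_ids)}
        nbins = default_nbins(blocks[0].n_samples)

        def mi_of(edges):
            return {(s, t): mutual_information(col[s], col[t], nbins)
                    for s, t, _ in edges}

        true_mi = mi_of(mi_dataset.truth["true_prior_edges"])
        decoy_mi = mi_of(mi_dataset.truth["decoy_prior_edges"])
        priors = RegulatoryPrior(mi_dataset.priors)
        th = prior_edge_thresholds(priors, blocks, nbins=nbins)
        types = {(s, t): ty for s, t, ty in (mi_dataset.truth["true_prior_edges"]
                                             + mi_dataset.truth["decoy_prior_edges"])}
        rate = lambda mis: np.mean([v >= th[types[k]] for k, v in mis.items()])
        assert rate(true_mi) > rate(decoy_mi)
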