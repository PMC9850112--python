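"""Feature-to-gene mapping, ORA, GSEA, Jaccard, clusters, exclusive categories."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sgccanet.enrichment import (EnrichmentResult, GeneSetDB,
                                 cluster_functions_by_components,
                                 exclusive_category_test, gsea_preranked,
                                 intersection_summary, jaccard,
                                 map_features_to_genes, ora)
from sgccanet.exceptions import DegenerateDataError, ValidationError

from oracles import hypergeom_upper_tail


@pytest.fixture()
def annotation():
    return pd.DataFrame([
        ("T0001", "transcript", "GENE0001", True),
        ("T0002", "transcript", "GENE0002", False),
        ("hsa-mir-34b", "mirna", "MIR34B", False),
        ("cg0000001", "cpg", "GENE0001", False),
        ("cg0000001", "cpg", "GENE0002", False),   # probe overlapping two genes
        ("cg0000002", "cpg", "GENE0002", False),
    ], columns=["feature", "omic_type", "gene", "is_tf"])


class TestFeatureMapping:
    def test_mirna_maps_by_direct_name(self, annotation):
        assert map_features_to_genes(["hsa-mir-34b"], annotation) == {"MIR34B"}

    def test_cpg_expands_to_all_overlapping_genes(self, annotation):
        assert map_features_to_genes(["cg0000001"], annotation) == {"GENE0001", "GENE0002"}

    def test_empty_input_and_unknown_features(self, annotation):
        assert map_features_to_genes([], annotation) == set()
        assert map_features_to_genes(["nope"], annotation) == set()


class TestORA:
    def test_closed_form_full_overlap(self):
        db = GeneSetDB(sets={"t": set("abcde")}, universe=set("abcdefghij"))
        r = ora(set("abcde"), db)[0]
        assert r.p == pytest.approx(1 / math.comb(10, 5), abs=1e-15)
        assert r.hits == frozenset("abcde")

    def test_zero_hits_give_p_one(self):
        db = GeneSetDB(sets={"t": set("ab")}, universe=set("abcdef"))
        r = ora({"c", "d"}, db)[0]
        assert r.p == 1.0 and not r.significant

    def test_default_alpha_is_one_percent_fdr(self):
        db = GeneSetDB(sets={"t": set("abcde"), "u": set("fg")},
                       universe=set("abcdefghij"))
        results = {r.term: r for r in ora(set("abcde"), db)}
        assert results["t"].significant          # fdr ~ 0.008 < 0.01
        assert not results["u"].significant

    def test_empty_query_raises(self):
        db = GeneSetDB(sets={"t": {"a"}}, universe={"a", "b"})
        with pytest.raises(ValidationError):
            ora({"z"}, db)

    def test_matches_direct_combinatorial_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            N = int(rng.integers(4, 31))
            genes = [f"g{i}" for i in range(N)]
            K = int(rng.integers(1, N + 1))
            m = int(rng.integers(1, N + 1))
            term = set(rng.choice(genes, K, replace=False))
            query = set(rng.choice(genes, m, replace=False))
            db = GeneSetDB(sets={"t": term}, universe=set(genes))
            r = ora(query, db)[0]
            k = len(query & term)
            assert r.p == pytest.approx(hypergeom_upper_tail(k, N, K, m), abs=1e-12)

    def test_bh_adjustment_never_below_raw_p(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(25)]
        sets = {f"t{i}": set(rng.choice(genes, int(rng.integers(3, 10)), replace=False))
                for i in range(8)}
        db = GeneSetDB(sets=sets, universe=set(genes))
        results = ora(set(rng.choice(genes, 10, replace=False)), db)
        ps = [r.p for r in results]
        qs = [r.fdr for r in results]
        assert all(q >= p - 1e-15 for p, q in zip(ps, qs))
        # results sorted by p => BH values monotone along that order
        assert all(qs[i] <= qs[i + 1] + 1e-15 for i in range(len(qs) - 1))


class TestGSEA:
    def test_five_gene_hand_unrolled_running_sum(self):
        # genes A..E, scores 5..1, set {A, C}: NR = 8
        # steps: +5/8, -1/3, +3/8, -1/3, -1/3
        # running: 0.625, 0.2917, 0.6667, 0.3333, 0  ->  ES = 2/3
        s = pd.Series([5.0, 4.0, 3.0, 2.0, 1.0], index=list("ABCDE"))
        db = GeneSetDB(sets={"x": {"A", "C"}}, universe=set("ABCDE"))
        out = gsea_preranked(s, db, n_perm=100, seed=0)
        assert out.es[0] == pytest.approx(2 / 3, abs=1e-15)

    def test_fixed_seed_reproduces_nes(self):
        rng = np.random.default_rng(3)
        s = pd.Series(rng.standard_normal(40), index=[f"g{i}" for i in range(40)])
        db = GeneSetDB(sets={"x": {f"g{i}" for i in range(0, 8)}}, universe=set(s.index))
        a = gsea_preranked(s, db, n_perm=200, seed=9)
        b = gsea_preranked(s, db, n_perm=200, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_negating_scores_flips_es_sign(self):
        rng = np.random.default_rng(4)
        s = pd.Series(rng.standard_normal(30), index=[f"g{i}" for i in range(30)])
        top = set(s.sort_values(ascending=False).index[:6])
        db = GeneSetDB(sets={"x": top}, universe=set(s.index))
        es_pos = gsea_preranked(s, db, n_perm=50, seed=0).es[0]
        es_neg = gsea_preranked(-s, db, n_perm=50, seed=0).es[0]
        assert np.sign(es_pos) == -np.sign(es_neg)

    def test_term_without_ranked_member_is_skipped(self):
        s = pd.Series([1.0, 0.5], index=["a", "b"])
        db = GeneSetDB(sets={"x": {"z"}, "y": {"a"}}, universe={"a", "b", "z"})
        out = gsea_preranked(s, db, n_perm=10, seed=0)
        assert list(out.term) == ["y"]


class TestJaccard:
    @pytest.mark.parametrize("a, b, expected", [
        ({"a", "b", "c"}, {"a", "b", "c"}, 1.0),
        ({"a"}, {"b"}, 0.0),
        ({"a", "b", "c"}, {"b", "c", "d"}, 0.5),
        (set(), {"a"}, 0.0),
    ])
    def test_known_values(self, a, b, expected):
        assert jaccard(a, b) == pytest.approx(expected)

    def test_both_empty_is_undefined(self):
        with pytest.raises(DegenerateDataError):
            jaccard(set(), set())

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.sets(st.integers(0, 10)), st.sets(st.integers(0, 10)))
    def test_bounded_and_symmetric(self, a, b):
        if not (a | b):
            return
        j = jaccard(a, b)
        assert 0 <= j <= 1
        assert j == jaccard(b, a)


def _res(term, components, significant=True, dataset=None, p=0.001):
    return EnrichmentResult(term=term, p=p, fdr=p, hits=frozenset({"g"}),
                            query_size=1, term_size=1, universe_size=10,
                            significant=significant,
                            components=frozenset(components), dataset=dataset)


class TestComponentClusters:
    def test_identical_component_sets_always_cluster(self):
        out = cluster_functions_by_components([_res("A", {1, 2}), _res("B", {1, 2})],
                                              tau=1.0)
        assert {"A", "B"} in out.clusters

    def test_hand_example_partial_overlap(self):
        results = [_res("A", {1, 2}), _res("B", {2, 3}), _res("C", {5})]
        out = cluster_functions_by_components(results, tau=0.3)
        assert {"A", "B"} in out.clusters and {"C"} in out.clusters
        assert out.unclustered == {"C"}

    def test_no_shared_components_means_singletons(self):
        out = cluster_functions_by_components([_res("A", {1}), _res("B", {2})], tau=0.5)
        assert out.unclustered == {"A", "B"}


class TestExclusiveCategories:
    def test_perfectly_split_classes_are_significant(self):
        classes = {f"a{i}": "X" for i in range(5)} | {f"b{i}": "Y" for i in range(5)}
        enr = {"d1": [_res(f"a{i}", {1}, dataset="d1") for i in range(5)],
               "d2": [_res(f"b{i}", {1}, dataset="d2") for i in range(5)]}
        out = exclusive_category_test(enr, classes)
        row = out[(out.term_class == "X") & (out.dataset == "d1")].iloc[0]
        # 2x2 table [[5,0],[0,5]]: two-sided Fisher p = 2 / C(10,5)
        assert row["p"] == pytest.approx(2 / math.comb(10, 5), abs=1e-12)
        assert row["p_bonferroni"] == pytest.approx(row["p"] * len(out))
        assert row["significant"]

    def test_evenly_spread_class_not_significant(self):
        classes = {f"t{i}": "X" for i in range(6)}
        enr = {"d1": [_res(f"t{i}", {1}, dataset="d1") for i in range(3)],
               "d2": [_res(f"t{i}", {1}, dataset="d2") for i in range(3, 6)]}
        out = exclusive_category_test(enr, classes)
        assert (out["p"] == 1.0).all()
        assert not out["significant"].any()

    def test_shared_terms_are_not_exclusive(self):
        classes = {"t": "X"}
        enr = {"d1": [_res("t", {1}, dataset="d1")],
               "d2": [_res("t", {1}, dataset="d2")]}
        out = exclusive_category_test(enr, classes)
        assert out.empty


class TestIntersectionSummary:
    def test_two_dataset_hand_counts(self):
        enr = {"d1": [_res("a", {1}), _res("b", {1})],
               "d2": [_res("b", {1}), _res("c", {1})]}
        membership, counts = intersection_summary(enr)
        assert membership.loc["b"].tolist() == [True, True]
        assert counts[("d1",)] == 1 and counts[("d2",)] == 1
        assert counts[("d1", "d2")] == 1

    def test_single_dataset_all_terms_in_one_pattern(self):
        enr = {"only": [_res("a", {1}), _res("b", {1})]}
        membership, counts = intersection_summary(enr)
        assert counts[("only",)] == 2 and len(counts) == 1
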