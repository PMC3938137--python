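import itertools
import math
from fractions import Fraction

import networkx as nx
import numpy as np
import pytest

from dmakit.enrichment import (enrich_gene_sets, enrich_go, export_go_graph,
                               hypergeom_pmf, hypergeom_tail,
                               propagate_annotations)
from dmakit.io import GeneSetCollection, OntologyGraph


def pmf_enumeration(x, M, K, n):
    """Exact pmf by enumerating all C(M, n) equally likely draws."""
    marked = set(range(K))
    hits = sum(1 for draw in itertools.combinations(range(M), n)
               if len(marked & set(draw)) == x)
    return Fraction(hits, math.comb(M, n))


def pmf_fraction(x, M, K, n):
    return Fraction(math.comb(K, x) * math.comb(M - K, n - x), math.comb(M, n))


class TestHypergeomPmf:
    def test_worked_example_small_draw(self):
        # 10 equally likely draws of 2 from 5 with 2 marked; 6 hit exactly 1
        assert hypergeom_pmf(1, 5, 2, 2) == pytest.approx(0.6, rel=1e-12)
        assert pmf_enumeration(1, 5, 2, 2) == Fraction(6, 10)

    def test_all_marked_gives_certainty(self):
        assert hypergeom_pmf(4, 7, 7, 4) == pytest.approx(1.0)

    @pytest.mark.parametrize("M", [5, 8, 12])
    def test_sums_to_one_over_support(self, M):
        for K in range(M + 1):
            for n in range(M + 1):
                lo, hi = max(0, n + K - M), min(n, K)
                total = math.fsum(hypergeom_pmf(x, M, K, n)
                                  for x in range(lo, hi + 1))
                assert total == pytest.approx(1.0, abs=1e-12)

    def test_out_of_support_arguments_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_pmf(3, 5, 2, 2)
        with pytest.raises(ValueError):
            hypergeom_pmf(0, 5, 6, 2)

    def test_log_and_exact_paths_agree(self):
        for M, K, n, x in [(60, 20, 15, 7), (200, 50, 40, 20),
                           (1000, 100, 80, 30)]:
            assert hypergeom_pmf(x, M, K, n, "log") == pytest.approx(
                hypergeom_pmf(x, M, K, n, "exact"), rel=1e-10)


class TestHypergeomTail:
    def test_single_term_tail(self):
        # P(X >= 2) with M=5, K=2, n=2 is the single term C(2,2)C(3,0)/C(5,2)
        assert hypergeom_tail(2, 5, 2, 2) == pytest.approx(0.1, rel=1e-12)

    def test_tail_at_support_minimum_is_one(self):
        assert hypergeom_tail(0, 30, 10, 5) == pytest.approx(1.0)

    def test_worked_example_66_over_252(self):
        assert hypergeom_tail(3, 10, 4, 5) == pytest.approx(66 / 252, rel=1e-12)

    def test_non_increasing_in_x(self):
        vals = [hypergeom_tail(x, 40, 12, 10) for x in range(0, 11)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_matches_scipy_survival_function(self):
        from scipy.stats import hypergeom
        for M, K, n in [(50, 10, 12), (500, 60, 45), (1000, 200, 100)]:
            for x in (1, 5, min(n, K)):
                expected = hypergeom.sf(x - 1, M, K, n)
                assert hypergeom_tail(x, M, K, n) == pytest.approx(
                    expected, rel=1e-9)


def toy_ontology():
    g = nx.DiGraph()
    for node, name in [("root", "root"), ("A", "branch A"), ("B", "branch B"),
                       ("C", "leaf C")]:
        g.add_node(node, name=name, namespace="toy")
    g.add_edge("A", "root")
    g.add_edge("B", "root")
    g.add_edge("C", "A")
    return g


class TestEnrichGeneSets:
    def test_worked_overlap_example(self):
        background = {f"g{i}" for i in range(10)}
        coll = GeneSetCollection({"S": ("", frozenset({"G0", "G1", "G2", "G3"}))})
        query = {"g0", "g1", "g2", "g8", "g9"}  # 3 of 5 hit the 4-gene set
        (rec,) = enrich_gene_sets(query, background, coll, p_cutoff=1.1)
        assert rec.K == 4 and rec.x == 3 and rec.n == 5 and rec.M == 10
        assert rec.p_value == pytest.approx(66 / 252, rel=1e-12)

    def test_query_equal_background_is_degenerate(self):
        background = {f"g{i}" for i in range(8)}
        coll = GeneSetCollection({"S": ("", frozenset({"G0", "G1"}))})
        (rec,) = enrich_gene_sets(background, background, coll, p_cutoff=1.1)
        assert rec.x == rec.K
        assert rec.p_value == pytest.approx(1.0)

    def test_gene_order_and_duplicates_irrelevant(self):
        background = [f"g{i}" for i in range(20)]
        coll = GeneSetCollection({"S": ("", frozenset({"G1", "G2", "G3"}))})
        q1 = ["g1", "g2", "g5", "g6"]
        q2 = ["g6", "g2", "g1", "g5", "G2", " g1 "]
        r1 = enrich_gene_sets(q1, background, coll, 1.1)
        r2 = enrich_gene_sets(q2, background, coll, 1.1)
        assert r1[0].p_value == r2[0].p_value
        assert r1[0].x == r2[0].x

    def test_empty_query_rejected(self):
        coll = GeneSetCollection({"S": ("", frozenset({"G1"}))})
        with pytest.raises(ValueError, match="query"):
            enrich_gene_sets([], {"g1"}, coll)

    def test_planted_set_ranks_first(self):
        from dmakit.simulate import gen_genesets_and_ontology
        coll, _onto, query, background, truth = \
            gen_genesets_and_ontology(seed=11)
        records = enrich_gene_sets(query, background, coll, p_cutoff=1.1)
        assert records[0].set_id == truth.planted_set


class TestEnrichGo:
    def test_annotation_propagates_to_ancestors(self):
        onto = OntologyGraph(toy_ontology(), {"G1": frozenset({"C"})})
        term_genes = propagate_annotations(onto)
        assert term_genes["C"] == {"G1"}
        assert term_genes["A"] == {"G1"}
        assert term_genes["root"] == {"G1"}
        assert term_genes["B"] == frozenset()

    def test_term_with_same_content_as_child_has_same_p(self):
        onto = OntologyGraph(toy_ontology(),
                             {"G1": frozenset({"C"}), "G2": frozenset({"C"}),
                              "G3": frozenset({"B"}), "G4": frozenset({"B"})})
        records = enrich_go({"g1", "g2"}, {"g1", "g2", "g3", "g4"}, onto,
                            p_cutoff=1.1)
        by_id = {r.set_id: r for r in records}
        assert by_id["C"].p_value == by_id["A"].p_value  # A's genes == C's

    def test_root_excluded_from_output(self):
        onto = OntologyGraph(toy_ontology(), {"G1": frozenset({"C"})})
        records = enrich_go({"g1"}, {"g1"}, onto, p_cutoff=1.1)
        assert all(r.set_id != "root" for r in records)

    def test_planted_leaf_and_ancestors_dominate(self):
        from dmakit.simulate import gen_genesets_and_ontology
        _coll, onto, query, background, truth = \
            gen_genesets_and_ontology(seed=11)
        records = enrich_go(query, background, onto, p_cutoff=1.1)
        assert records[0].set_id == truth.planted_term
        lineage = onto.ancestors(truth.planted_term) - onto.roots
        top_ids = {r.set_id for r in records[: 1 + len(lineage)]}
        assert lineage <= top_ids


class TestExportGoGraph:
    def test_nodes_are_significant_terms_plus_ancestry(self, tmp_path):
        onto = OntologyGraph(toy_ontology(), {"G1": frozenset({"C"})})
        records = enrich_go({"g1"}, {"g1", "g2"}, onto, p_cutoff=1.1)
        sig_c = [r for r in records if r.set_id == "C"]
        path = tmp_path / "go.dot"
        export_go_graph(sig_c, onto, path)
        text = path.read_text()
        assert '"C"' in text and '"A"' in text and '"root"' in text
        assert '"B"' not in text
        assert '"C" -> "A"' in text and '"A" -> "root"' in text

    def test_empty_records_give_empty_graph(self, tmp_path):
        onto = OntologyGraph(toy_ontology(), {})
        path = tmp_path / "go.dot"
        export_go_graph([], onto, path)
        text = path.read_text()
        assert "->" not in text
        assert '"A"' not in text


class TestNullCalibration:
    def test_unplanted_pvalues_are_valid(self):
        """Nominal hypergeometric p-values of random (unplanted) sets are
        conservative: P(p <= t) <= t plus binomial slack."""
        from dmakit.simulate import gen_genesets_and_ontology
        pvals = []
        for seed in range(100):
            coll, _o, query, background, truth = \
                gen_genesets_and_ontology(seed=seed)
            records = enrich_gene_sets(query, background, coll, p_cutoff=1.1)
            pvals.extend(r.p_value for r in records
                         if r.set_id != truth.planted_set)
        pvals = np.asarray(pvals)
        for t in (0.01, 0.05, 0.1, 0.25, 0.5):
            frac = float((pvals <= t).mean())
            slack = 3 * math.sqrt(t * (1 - t) / pvals.size)
            assert frac <= t + slack
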