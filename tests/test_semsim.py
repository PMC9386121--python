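"""Term-, gene- and set-level similarity: hand values, oracles, laws."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import semlink as sl
from semlink.semsim import DEFAULT_WANG_WEIGHTS, _wang_svalues

LN2 = math.log(2)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def naive_bma(matrix) -> float:
    """Best-match average spelled out with explicit loops."""
    n, m = len(matrix), len(matrix[0])
    total = 0.0
    for i in range(n):
        best = 0.0
        for j in range(m):
            best = max(best, matrix[i][j])
        total += best
    for j in range(m):
        best = 0.0
        for i in range(n):
            best = max(best, matrix[i][j])
        total += best
    return total / (n + m)


def path_product_svalues(dag, term, weights=DEFAULT_WANG_WEIGHTS):
    """S-values via brute-force path enumeration: the S-value of an
    ancestor is the maximum over all upward paths of the product of edge
    weights along the path."""
    best = {term: 1.0}

    def walk(node, product):
        for parent, rel in dag.terms[node].parents:
            p = product * weights.weight(rel)
            if p > best.get(parent, 0.0):
                best[parent] = p
            walk(parent, p)

    walk(term, 1.0)
    return best


def wang_oracle(dag, t1, t2, weights=DEFAULT_WANG_WEIGHTS) -> float:
    s1 = path_product_svalues(dag, t1, weights)
    s2 = path_product_svalues(dag, t2, weights)
    common = s1.keys() & s2.keys()
    if not common:
        return 0.0
    return (sum(s1[a] + s2[a] for a in common)
            / (sum(s1.values()) + sum(s2.values())))


# ---------------------------------------------------------------------------
# MICA and IC-based term similarity
# ---------------------------------------------------------------------------

class TestMica:
    def test_subsumer_can_be_its_own_mica(self, d5_dag, d5_ic):
        assert sl.mica(d5_dag, d5_ic, "A", "C") == ("A", pytest.approx(LN2))

    def test_root_only_overlap(self, d5_dag, d5_ic):
        term, value = sl.mica(d5_dag, d5_ic, "A", "B")
        assert term == "R" and value == 0.0

    def test_self_mica(self, d5_dag, d5_ic):
        assert sl.mica(d5_dag, d5_ic, "C", "C") == ("C", pytest.approx(2 * LN2))

    def test_tie_broken_by_smallest_term_id(self):
        # two common ancestors with identical IC: the smaller id wins
        dag = sl.OntologyDAG([
            sl.OntologyTerm("R", namespace="BP"),
            sl.OntologyTerm("P1", namespace="BP", parents=(("R", "is_a"),)),
            sl.OntologyTerm("P2", namespace="BP", parents=(("R", "is_a"),)),
            sl.OntologyTerm("X", namespace="BP",
                            parents=(("P1", "is_a"), ("P2", "is_a"))),
            sl.OntologyTerm("Y", namespace="BP",
                            parents=(("P1", "is_a"), ("P2", "is_a"))),
        ])
        corpus = sl.propagate_counts(dag, {"g1": {"X"}, "g2": {"Y"}})
        ic = sl.compute_ic(corpus, "BP")
        term, _ = sl.mica(dag, ic, "X", "Y")
        assert term == "P1"

    def test_cross_namespace_error(self):
        dag = sl.OntologyDAG([sl.OntologyTerm("R1", namespace="BP"),
                              sl.OntologyTerm("R2", namespace="MF")])
        corpus = sl.propagate_counts(dag, {"g": {"R1"}})
        ic = sl.compute_ic(corpus, "BP")
        with pytest.raises(ValueError, match="common ancestor"):
            sl.mica(dag, ic, "R1", "R2")


class TestTermSimIC:
    @pytest.mark.parametrize("method, expected", [
        ("resnik", 0.5),
        ("lin", 2 * LN2 / (3 * LN2)),
        ("jiang", 1 - LN2),
        ("rel", (2 / 3) * 0.5),
    ])
    def test_hand_values_on_fixture(self, d5_dag, d5_ic, method, expected):
        value = sl.term_sim_ic(d5_dag, d5_ic, "A", "C", method)
        assert value == pytest.approx(expected, abs=1e-6)

    def test_root_only_overlap_scores_zero(self, d5_dag, d5_ic):
        assert sl.term_sim_ic(d5_dag, d5_ic, "A", "B", "lin") == 0.0

    def test_unannotated_term_is_an_error(self, d5_dag, d5_ic):
        with pytest.raises(ValueError, match="unannotated"):
            sl.term_sim_ic(d5_dag, d5_ic, "D", "C", "lin")

    def test_lin_self_similarity_is_one_even_at_root(self, d5_dag, d5_ic):
        assert sl.term_sim_ic(d5_dag, d5_ic, "R", "R", "lin") == 1.0
        assert sl.term_sim_ic(d5_dag, d5_ic, "C", "C", "lin") == 1.0

    def test_rel_self_similarity_is_one_minus_p(self, d5_dag, d5_ic):
        # the relevance measure discounts by the MICA's annotation
        # probability, so even identical terms score 1 - p(t)
        value = sl.term_sim_ic(d5_dag, d5_ic, "C", "C", "rel")
        assert value == pytest.approx(1 - math.exp(-d5_ic["C"]), abs=1e-12)


class TestTermSimWang:
    def test_hand_value_on_fixture(self, d5_dag):
        value = sl.term_sim_wang(d5_dag, "A", "C")
        assert value == pytest.approx(3.24 / 4.24, abs=1e-6)

    def test_identity(self, d5_dag):
        assert sl.term_sim_wang(d5_dag, "C", "C") == 1.0

    def test_siblings_under_one_parent(self):
        dag = sl.OntologyDAG([
            sl.OntologyTerm("R", namespace="BP"),
            sl.OntologyTerm("P", namespace="BP", parents=(("R", "is_a"),)),
            sl.OntologyTerm("X", namespace="BP", parents=(("P", "is_a"),)),
            sl.OntologyTerm("Y", namespace="BP", parents=(("P", "is_a"),)),
        ])
        expected = (0.8 + 0.8 + 0.64 + 0.64) / (2.44 + 2.44)
        assert sl.term_sim_wang(dag, "X", "Y") == pytest.approx(expected,
                                                                abs=1e-6)

    def test_part_of_edges_use_their_own_weight(self, d5_dag):
        svalues = _wang_svalues(d5_dag, "D", DEFAULT_WANG_WEIGHTS)
        assert svalues == pytest.approx({"D": 1.0, "A": 0.6, "R": 0.48})

    def test_disjoint_closures_score_zero_not_error(self):
        dag = sl.OntologyDAG([sl.OntologyTerm("R1", namespace="BP"),
                              sl.OntologyTerm("R2", namespace="MF")])
        assert sl.term_sim_wang(dag, "R1", "R2") == 0.0

    def test_matches_path_product_oracle_on_random_dags(self):
        rng = np.random.default_rng(17)
        for seed in range(10):
            dag = sl.generate_dag(50, max_parents=2, seed=seed)
            ids = sorted(dag.terms)
            for _ in range(30):
                t1, t2 = (ids[int(i)] for i in rng.integers(len(ids), size=2))
                assert sl.term_sim_wang(dag, t1, t2) == pytest.approx(
                    wang_oracle(dag, t1, t2), abs=1e-12)


# ---------------------------------------------------------------------------
# combination rules
# ---------------------------------------------------------------------------

class TestBMA:
    def test_hand_value(self):
        assert sl.bma([[1.0, 0.2], [0.4, 0.6]]) == pytest.approx(0.8)

    def test_all_ones(self):
        assert sl.bma(np.ones((3, 5))) == 1.0

    def test_single_pair(self):
        assert sl.bma([[0.3]]) == pytest.approx(0.3)

    def test_empty_matrix_is_an_error(self):
        with pytest.raises(ValueError):
            sl.bma(np.empty((0, 3)))

    @settings(derandomize=True, max_examples=80)
    @given(st.integers(1, 4), st.integers(1, 4), st.integers(0, 2 ** 31 - 1))
    def test_matches_naive_formula_and_bounds(self, n, m, seed):
        matrix = np.random.default_rng(seed).random((n, m))
        value = sl.bma(matrix)
        assert value == pytest.approx(naive_bma(matrix.tolist()), abs=1e-12)
        assert matrix.min() - 1e-12 <= value <= matrix.max() + 1e-12

    def test_alternative_combine_rules(self):
        matrix = [[1.0, 0.2], [0.4, 0.6]]
        assert sl.combine(matrix, "max") == 1.0
        assert sl.combine(matrix, "avg") == pytest.approx(0.55)
        assert sl.combine(matrix, "rcmax") == pytest.approx(0.8)


# ---------------------------------------------------------------------------
# gene- and set-level similarity
# ---------------------------------------------------------------------------

class TestGeneSim:
    def test_single_term_pair_reduces_to_term_sim(self, d5_dag, d5_ic):
        value = sl.gene_sim({"C"}, {"A"}, "lin", d5_dag, d5_ic)
        assert value == pytest.approx(2 / 3, abs=1e-6)

    def test_identical_term_sets_wang(self, d5_dag):
        assert sl.gene_sim({"A", "C"}, {"A", "C"}, "wang", d5_dag) == 1.0

    def test_root_only_overlap_is_zero(self, d5_dag, d5_ic):
        assert sl.gene_sim({"C"}, {"B"}, "lin", d5_dag, d5_ic) == 0.0


class TestSetSim:
    def test_all_root_overlaps_give_zero_sss(self, d5_corpus, d5_ic):
        result = sl.set_sim({"g1", "g2"}, {"g3", "g4"}, d5_corpus,
                            ic=d5_ic, method="lin")
        assert np.all(result.matrix == 0.0)
        assert result.sss == 0.0

    def test_self_comparison_is_one_for_wang(self, d5_corpus):
        result = sl.set_sim({"g1", "g2"}, {"g1", "g2"}, d5_corpus,
                            method="wang")
        assert result.sss == pytest.approx(1.0)

    def test_pairwise_reduces_to_gene_sim(self, d5_corpus, d5_ic):
        result = sl.set_sim(["g1"], ["g2"], d5_corpus, ic=d5_ic, method="lin")
        assert result.sss == pytest.approx(2 / 3, abs=1e-6)

    def test_sss_rederivable_as_bma_of_matrix(self, d5_corpus, d5_ic):
        result = sl.set_sim({"g1", "g2"}, {"g3", "g4", "g1"}, d5_corpus,
                            ic=d5_ic, method="jiang")
        assert result.sss == pytest.approx(sl.bma(result.matrix))

    def test_unannotated_genes_dropped_and_counted(self, d5_corpus, d5_ic):
        result = sl.set_sim({"g1", "ghost"}, {"g2"}, d5_corpus, ic=d5_ic,
                            method="lin")
        assert result.dropped_a == ("ghost",)
        assert result.set_a == ["g1"]

    def test_fully_unannotated_side_is_an_error(self, d5_corpus, d5_ic):
        with pytest.raises(ValueError, match="unannotated"):
            sl.set_sim({"ghost"}, {"g2"}, d5_corpus, ic=d5_ic, method="lin")

    def test_symmetry_of_sss(self, d5_corpus, d5_ic):
        for method in sl.METHODS:
            ic = d5_ic if method != "wang" else None
            ab = sl.set_sim({"g1", "g2"}, {"g3", "g4"}, d5_corpus, ic=d5_ic,
                            method=method)
            ba = sl.set_sim({"g3", "g4"}, {"g1", "g2"}, d5_corpus, ic=d5_ic,
                            method=method)
            assert ab.sss == pytest.approx(ba.sss, abs=1e-12)

    def test_matrix_tsv_roundtrip(self, d5_corpus, d5_ic, tmp_path):
        import pandas as pd
        result = sl.set_sim({"g1", "g2"}, {"g3", "g4"}, d5_corpus,
                            ic=d5_ic, method="lin")
        path = tmp_path / "matrix.tsv"
        result.to_tsv(path)
        frame = pd.read_csv(path, sep="\t", index_col=0)
        assert list(frame.index) == result.set_a
        assert list(frame.columns) == result.set_b


class TestMeasureLaws:
    """Symmetry, identity and range across random ontologies."""

    def test_laws_on_random_term_pairs(self):
        rng = np.random.default_rng(23)
        for seed in range(5):
            dag = sl.generate_dag(80, seed=seed)
            corpus = sl.generate_corpus(dag, 300, seed=seed + 100)
            ic = sl.compute_ic(corpus, "BP")
            annotated = sorted(ic.ic)
            engines = {m: sl.SimilarityEngine(
                dag, ic if m != "wang" else None, m, namespace="BP")
                for m in sl.METHODS}
            for _ in range(100):
                t1, t2 = (annotated[int(i)]
                          for i in rng.integers(len(annotated), size=2))
                for method, engine in engines.items():
                    v12 = engine.term_sim(t1, t2)
                    v21 = engine.term_sim(t2, t1)
                    assert v12 == v21
                    assert 0.0 <= v12 <= 1.0
            for t in (annotated[int(i)]
                      for i in rng.integers(len(annotated), size=20)):
                for method in ("lin", "jiang", "wang"):
                    assert engines[method].term_sim(t, t) == pytest.approx(1.0)
                assert engines["rel"].term_sim(t, t) == pytest.approx(
                    1 - math.exp(-ic[t]), abs=1e-12)
                assert engines["resnik"].term_sim(t, t) == pytest.approx(
                    ic[t] / ic.max_ic, abs=1e-12)
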