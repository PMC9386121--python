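"""Rank-sum differential expression and hypergeometric enrichment."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy.stats import rankdata

import semlink as sl


def enumeration_p(x, y, alternative="two_sided"):
    """Exact rank-sum p by brute force over all C(n1+n2, n1) splits."""
    pooled = list(x) + list(y)
    n1 = len(x)
    ranks = rankdata(pooled)
    null_us = []
    for chosen in combinations(range(len(pooled)), n1):
        r1 = sum(ranks[i] for i in chosen)
        null_us.append(r1 - n1 * (n1 + 1) / 2)
    null_us = np.asarray(null_us)
    u_obs = sum(ranks[:n1]) - n1 * (n1 + 1) / 2
    p_ge = float(np.mean(null_us >= u_obs))
    p_le = float(np.mean(null_us <= u_obs))
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2 * min(p_ge, p_le))


class TestWilcoxonRankSum:
    def test_fully_separated_samples(self):
        u, p = sl.wilcoxon_ranksum([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_multisets_are_null(self):
        _, p = sl.wilcoxon_ranksum([1, 2, 3, 4], [1, 2, 3, 4])
        assert p == pytest.approx(1.0, abs=0.05)

    def test_constant_data_gives_p_one(self):
        u, p = sl.wilcoxon_ranksum([5, 5, 5], [5, 5])
        assert p == 1.0
        assert u == 3.0  # the null mean of U

    def test_empty_sample_is_an_error(self):
        with pytest.raises(ValueError):
            sl.wilcoxon_ranksum([], [1.0])

    def test_swap_symmetry(self):
        rng = np.random.default_rng(1)
        x, y = list(rng.normal(size=5)), list(rng.normal(size=7))
        u_xy, p_xy = sl.wilcoxon_ranksum(x, y)
        u_yx, p_yx = sl.wilcoxon_ranksum(y, x)
        assert u_yx == pytest.approx(len(x) * len(y) - u_xy)
        assert p_xy == pytest.approx(p_yx)

    @pytest.mark.parametrize("n", [3, 4])
    @pytest.mark.parametrize("alternative", ["two_sided", "less", "greater"])
    def test_exact_p_equals_enumeration(self, n, alternative):
        rng = np.random.default_rng(42 + n)
        for _ in range(10):
            values = rng.choice(10_000, size=2 * n, replace=False)
            x, y = list(values[:n].astype(float)), list(
                values[n:].astype(float))
            _, p = sl.wilcoxon_ranksum(x, y, alternative)
            assert p == pytest.approx(enumeration_p(x, y, alternative),
                                      abs=1e-12)


class TestDiffExpression:
    def test_planted_shift_detected_with_direction(self):
        expr, truth = sl.generate_expression(n_genes=30, de_gene_effect=3.0,
                                             seed=9)
        u, p, direction = sl.diff_expression(expr, truth.de_gene)
        assert p < 0.05
        assert direction == 1

    def test_unknown_gene_is_an_error(self):
        expr, _ = sl.generate_expression(n_genes=5, seed=0)
        with pytest.raises(KeyError):
            sl.diff_expression(expr, "nope")

    def test_constant_gene_gives_p_one(self):
        import pandas as pd
        values = pd.DataFrame(np.zeros((1, 6)), index=["g"],
                              columns=[f"s{i}" for i in range(6)])
        groups = {f"s{i}": ("case" if i < 3 else "control") for i in range(6)}
        expr = sl.ExpressionMatrix(values=values, groups=groups)
        _, p, direction = sl.diff_expression(expr, "g")
        assert p == 1.0
        assert direction == 0

    def test_null_gene_small_power(self):
        """A non-planted gene should rarely look significant."""
        hits = 0
        for seed in range(20):
            expr, truth = sl.generate_expression(n_genes=10, seed=seed)
            genes = [g for g in expr.genes if g != truth.de_gene]
            _, p, _ = sl.diff_expression(expr, genes[0])
            hits += p <= 0.05
        assert hits <= 4


class TestExpressionMatrix:
    def test_missing_values_rejected(self):
        import pandas as pd
        values = pd.DataFrame([[1.0, np.nan]], index=["g"],
                              columns=["s1", "s2"])
        with pytest.raises(ValueError, match="missing"):
            sl.ExpressionMatrix(values=values,
                                groups={"s1": "case", "s2": "control"})

    def test_both_groups_required(self):
        import pandas as pd
        values = pd.DataFrame([[1.0, 2.0]], index=["g"],
                              columns=["s1", "s2"])
        with pytest.raises(ValueError, match="nonempty"):
            sl.ExpressionMatrix(values=values,
                                groups={"s1": "case", "s2": "case"})

    def test_roundtrip_through_writers(self, tmp_path):
        from semlink.synthetic import write_expression
        expr, _ = sl.generate_expression(n_genes=8, n_case=3, n_control=4,
                                         seed=2)
        write_expression(expr, tmp_path / "e.tsv", tmp_path / "g.tsv")
        loaded = sl.load_expression(tmp_path / "e.tsv", tmp_path / "g.tsv")
        assert loaded.genes == expr.genes
        assert loaded.groups == expr.groups
        np.testing.assert_allclose(loaded.values.to_numpy(),
                                   expr.values.to_numpy(), rtol=1e-6)


@pytest.fixture(scope="module")
def two_term_corpus():
    dag = sl.OntologyDAG([
        sl.OntologyTerm("R", namespace="BP"),
        sl.OntologyTerm("X", namespace="BP", parents=(("R", "is_a"),)),
    ])
    direct = {f"g{i}": {"X"} for i in range(5)}
    direct.update({f"h{i}": {"R"} for i in range(15)})
    return sl.propagate_counts(dag, direct)


class TestEnrichment:
    def test_closed_form_hypergeometric(self, two_term_corpus):
        rows = sl.enrich_hypergeometric({f"g{i}" for i in range(5)},
                                        two_term_corpus)
        by_term = {row.term_id: row for row in rows}
        assert by_term["X"].p == pytest.approx(1 / math.comb(20, 5),
                                               rel=1e-9)
        assert (by_term["X"].k, by_term["X"].K, by_term["X"].n,
                by_term["X"].N) == (5, 5, 5, 20)

    def test_zero_overlap_gives_p_one(self, two_term_corpus):
        rows = sl.enrich_hypergeometric({f"h{i}" for i in range(5)},
                                        two_term_corpus)
        by_term = {row.term_id: row for row in rows}
        assert by_term["X"].p == pytest.approx(1.0)

    def test_rows_sorted_by_p_then_term(self, two_term_corpus):
        rows = sl.enrich_hypergeometric({f"g{i}" for i in range(3)},
                                        two_term_corpus)
        ps = [row.p for row in rows]
        assert ps == sorted(ps)

    def test_adjusted_p_never_below_raw(self):
        dag = sl.generate_dag(40, seed=8)
        corpus = sl.generate_corpus(dag, 100, seed=9)
        rows = sl.enrich_hypergeometric(set(sorted(corpus.universe)[:12]),
                                        corpus)
        assert all(row.p_adj >= row.p - 1e-15 for row in rows)
        assert max(row.p_adj for row in rows) == pytest.approx(
            max(row.p for row in rows))

    def test_empty_usable_set_is_an_error(self, two_term_corpus):
        with pytest.raises(ValueError):
            sl.enrich_hypergeometric({"ghost"}, two_term_corpus)


class TestBenjaminiHochberg:
    def test_hand_computed_adjustment(self):
        np.testing.assert_allclose(sl.adjust_bh([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_never_decreases_and_preserves_max(self):
        rng = np.random.default_rng(6)
        raw = rng.random(20)
        adjusted = sl.adjust_bh(raw)
        assert np.all(adjusted >= raw - 1e-15)
        assert adjusted.max() == pytest.approx(raw.max())
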