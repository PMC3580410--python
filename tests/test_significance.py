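from itertools import combinations

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import netsig as ns
from netsig.significance import NullDistribution


@pytest.fixture
def survival_expr(rng):
    vals = rng.standard_normal((12, 30))
    return ns.ExpressionDataset(
        genes=[f"g{i}" for i in range(12)],
        samples=[f"s{j}" for j in range(30)],
        values=vals,
        time=rng.exponential(5, 30) + 0.1,
        event=(rng.random(30) < 0.6).astype(int))


class TestPermuteExpression:
    def test_deterministic_under_seed(self, survival_expr):
        a = ns.permute_expression(survival_expr, seed=5)
        b = ns.permute_expression(survival_expr, seed=5)
        np.testing.assert_array_equal(a.values, b.values)

    def test_row_multiset_conserved(self, survival_expr):
        perm = ns.permute_expression(survival_expr, seed=3)
        orig = {tuple(r) for r in survival_expr.values}
        new = {tuple(r) for r in perm.values}
        assert orig == new
        assert not np.array_equal(perm.values, survival_expr.values)

    def test_survival_columns_unchanged(self, survival_expr):
        perm = ns.permute_expression(survival_expr, seed=3)
        np.testing.assert_array_equal(perm.time, survival_expr.time)
        np.testing.assert_array_equal(perm.event, survival_expr.event)

    def test_within_row_mode_preserves_each_row_multiset(self, survival_expr):
        perm = ns.permute_expression(survival_expr, seed=3, mode="within_row")
        for a, b in zip(survival_expr.values, perm.values):
            assert sorted(a) == sorted(b)


class TestRandomGeneSetNull:
    def test_zero_trials_empty(self, survival_expr):
        net = nx.complete_graph([f"g{i}" for i in range(12)])
        null = ns.random_gene_set_null(net, 3, survival_expr,
                                       survival_expr.time,
                                       survival_expr.event, 0, seed=1)
        assert len(null.values) == 0

    def test_seed_reproducibility(self, survival_expr):
        net = nx.complete_graph([f"g{i}" for i in range(12)])
        a = ns.random_gene_set_null(net, 3, survival_expr, survival_expr.time,
                                    survival_expr.event, 10, seed=2)
        b = ns.random_gene_set_null(net, 3, survival_expr, survival_expr.time,
                                    survival_expr.event, 10, seed=2)
        np.testing.assert_array_equal(a.values, b.values)

    def test_oversized_set_rejected(self, survival_expr):
        net = nx.complete_graph([f"g{i}" for i in range(12)])
        with pytest.raises(ValueError, match="exceeds"):
            ns.random_gene_set_null(net, 13, survival_expr,
                                    survival_expr.time, survival_expr.event,
                                    1, seed=1)

    def test_null_p_roughly_uniform_on_noise(self):
        # pure-noise expression: P-values of random-set scores ~ U(0,1)
        rng = np.random.default_rng(0)
        n = 150
        expr = ns.ExpressionDataset(
            genes=[f"g{i}" for i in range(40)],
            samples=[f"s{j}" for j in range(n)],
            values=rng.standard_normal((40, n)),
            time=rng.exponential(10, n) + 0.01,
            event=(rng.random(n) < 0.6).astype(int))
        net = nx.complete_graph([f"g{i}" for i in range(40)])
        null = ns.random_gene_set_null(net, 8, expr, expr.time, expr.event,
                                       1000, seed=4)
        frac = float((null.values < 0.05).mean())
        se = np.sqrt(0.05 * 0.95 / 1000)
        assert abs(frac - 0.05) < 2.5 * se + 0.01


class TestEmpiricalP:
    def make_null(self, values):
        return NullDistribution("stat", np.asarray(values, dtype=float),
                                len(values), seed=0)

    def test_add_one_formula(self):
        null = self.make_null(np.linspace(0.5, 1.0, 1000))
        assert ns.empirical_pvalue(0.01, null) == pytest.approx(1 / 1001)

    def test_observed_equal_to_all_null_values(self):
        null = self.make_null([0.3] * 10)
        assert ns.empirical_pvalue(0.3, null) == 1.0

    def test_half_extreme(self):
        null = self.make_null(list(np.arange(1, 100) / 100))
        assert ns.empirical_pvalue(0.495, null) == pytest.approx(0.5)

    def test_bounds_and_monotonicity(self):
        null = self.make_null([0.2, 0.4, 0.6])
        p = ns.empirical_pvalue(0.3, null)
        assert 0 < p <= 1
        bigger = self.make_null([0.2, 0.4, 0.6, 0.05])
        assert ns.empirical_pvalue(0.3, bigger) >= p


class TestHypergeometricOverlap:
    def test_empty_overlap_is_one(self):
        bg = set(range(20))
        assert ns.hypergeometric_overlap({0, 1}, {5, 6}, bg) == 1.0

    def test_full_overlap_small_universe(self):
        bg = set(range(10))
        A = set(range(5))
        assert ns.hypergeometric_overlap(A, A, bg) == pytest.approx(1 / 252)

    def test_identity_sets_give_one(self):
        bg = set(range(6))
        assert ns.hypergeometric_overlap(bg, bg, bg) == pytest.approx(1.0)

    def test_not_in_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            ns.hypergeometric_overlap({1, 99}, {1}, set(range(10)))

    @pytest.mark.parametrize("N,K,n", [(8, 3, 4), (10, 5, 5), (12, 6, 3)])
    def test_agrees_with_exhaustive_enumeration(self, N, K, n, rng):
        background = set(range(N))
        B = set(rng.choice(N, size=K, replace=False).tolist())
        A = set(rng.choice(N, size=n, replace=False).tolist())
        k = len(A & B)
        count = sum(1 for draw in combinations(range(N), n)
                    if len(set(draw) & B) >= k)
        from math import comb
        expected = count / comb(N, n)
        assert ns.hypergeometric_overlap(A, B, background) == \
            pytest.approx(expected, rel=1e-12)


class TestPvalueScore:
    def test_mean_of_exponents(self):
        assert ns.pvalue_score([1e-2, 1e-4]) == pytest.approx(3.0)

    def test_constant_list(self):
        assert ns.pvalue_score([0.05, 0.05, 0.05]) == \
            pytest.approx(-np.log10(0.05))

    def test_rejects_zero(self):
        with pytest.raises(ValueError):
            ns.pvalue_score([0.5, 0.0])

    @settings(derandomize=True, max_examples=30, database=None)
    @given(st.lists(st.floats(1e-10, 1.0), min_size=2, max_size=8),
           st.randoms(use_true_random=False))
    def test_permutation_invariant_and_monotone(self, ps, rnd):
        base = ns.pvalue_score(ps)
        shuffled = list(ps)
        rnd.shuffle(shuffled)
        assert ns.pvalue_score(shuffled) == pytest.approx(base, rel=1e-12)
        smaller = list(ps)
        smaller[0] = smaller[0] / 2
        assert ns.pvalue_score(smaller) > base


def test_bonferroni():
    assert ns.bonferroni(1e-3, 27) == pytest.approx(0.027)
    assert ns.bonferroni(0.5, 10) == 1.0
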