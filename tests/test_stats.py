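"""Statistical primitives against hand-derived values and small oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genegap.stats import (ContingencyTable, bh_fdr, bh_reject,
                           bootstrap_spearman_ci, common_language_f,
                           fisher_exact, mann_whitney_u, odds_ratio_ci,
                           percentile_rank, spearman_rho)


class TestMannWhitney:
    def test_identical_samples_centered(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(4.5)
        assert res.p_value == pytest.approx(1.0, abs=0.05)

    def test_complete_separation_exact_p(self):
        # all C(4,2)=6 rank assignments; U=0 is one of two extreme tables
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(2 / 6)

    def test_empty_group_named_in_error(self):
        with pytest.raises(ValueError, match="'y'"):
            mann_whitney_u([1.0], [])
        with pytest.raises(ValueError, match="'x'"):
            mann_whitney_u([], [1.0])

    def test_exact_matches_rank_enumeration(self):
        """Exact p equals the fraction of rank splits at least as extreme."""
        rng = np.random.default_rng(7)
        for n1, n2 in [(3, 3), (4, 5), (2, 6)]:
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            res = mann_whitney_u(x, y)
            p_oracle = _mwu_enumeration_p(x, y)
            assert res.p_value == pytest.approx(p_oracle, rel=1e-9)


def _mwu_enumeration_p(x, y):
    """Two-sided exact Mann-Whitney p by enumerating all rank assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    n = len(pooled)
    mean_u = n1 * (n - n1) / 2
    stat_obs = abs(u_obs - mean_u)
    count = 0
    total = 0
    for idx in itertools.combinations(range(n), n1):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        u = sum(1 for xi in xs for yj in ys if xi > yj)
        if abs(u - mean_u) >= stat_obs - 1e-12:
            count += 1
        total += 1
    return count / total


class TestCommonLanguageF:
    def test_symmetry_and_separation(self):
        assert common_language_f([1, 2, 3], [1, 2, 3]) == pytest.approx(0.5)
        assert common_language_f([5, 6], [1, 2]) == 1.0
        assert common_language_f([2, 4], [1, 3]) == pytest.approx(0.75)

    def test_equals_pair_enumeration(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 5, size=9).astype(float)  # ties on purpose
        y = rng.integers(0, 5, size=7).astype(float)
        pairs = [(xi, yj) for xi in x for yj in y]
        f_oracle = (sum(a > b for a, b in pairs)
                    + 0.5 * sum(a == b for a, b in pairs)) / len(pairs)
        assert common_language_f(x, y) == pytest.approx(f_oracle)

    @given(st.lists(st.integers(0, 1000), min_size=1, max_size=15, unique=True)
           .flatmap(lambda xs: st.tuples(
               st.just(xs),
               st.lists(st.integers(1001, 2000), min_size=1, max_size=15,
                        unique=True))))
    @settings(deadline=None, max_examples=50)
    def test_complementarity(self, xy):
        x, y = xy
        assert common_language_f(x, y) + common_language_f(y, x) == pytest.approx(1.0)


class TestOddsRatio:
    def test_independence_and_woolf_example(self):
        assert odds_ratio_ci(ContingencyTable(10, 10, 10, 10)).effect == 1.0
        res = odds_ratio_ci(ContingencyTable(20, 5, 10, 15))
        assert res.effect == pytest.approx(6.0)
        # direct Woolf: exp(ln 6 +- 1.96*sqrt(1/20+1/5+1/10+1/15))
        se = math.sqrt(1 / 20 + 1 / 5 + 1 / 10 + 1 / 15)
        assert res.ci_low == pytest.approx(6 * math.exp(-1.959964 * se), rel=1e-4)
        assert res.ci_high == pytest.approx(6 * math.exp(1.959964 * se), rel=1e-4)
        assert res.ci_low == pytest.approx(1.69, abs=0.01)
        assert res.ci_high == pytest.approx(21.3, abs=0.05)

    def test_zero_cell_haldane_flagged(self):
        res = odds_ratio_ci(ContingencyTable(5, 0, 2, 7))
        assert "haldane_correction" in res.flags
        assert res.effect == pytest.approx((5.5 * 7.5) / (0.5 * 2.5))

    def test_degenerate_margin_undefined(self):
        res = odds_ratio_ci(ContingencyTable(0, 0, 5, 5))
        assert "undefined_effect" in res.flags
        assert np.isnan(res.effect)

    def test_swapping_columns_within_rows_gives_reciprocal(self):
        t = ContingencyTable(12, 3, 7, 9)
        swapped = ContingencyTable(3, 12, 9, 7)
        assert odds_ratio_ci(swapped).effect == pytest.approx(
            1.0 / odds_ratio_ci(t).effect)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)


class TestFisherExact:
    @pytest.mark.parametrize("table,expected", [
        ((1, 1, 1, 1), 1.0),
        ((3, 0, 0, 3), 2 / 20),
        ((5, 0, 0, 5), 2 / 252),
    ])
    def test_enumerable_tables(self, table, expected):
        res = fisher_exact(ContingencyTable(*table))
        assert res.p_value == pytest.approx(expected, rel=1e-7)


class TestBH:
    def test_definition_examples(self):
        assert bh_fdr([0.5] * 5) == pytest.approx([0.5] * 5)
        assert not bh_reject([0.5] * 5, 0.05).any()
        assert bh_reject([0.01, 0.02, 0.03, 0.04], 0.05).all()
        assert bh_fdr([0.001, 0.04, 0.9]) == pytest.approx([0.003, 0.06, 0.9])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_monotone_and_permutation_invariant(self, ps):
        q = bh_fdr(ps)
        order = np.argsort(ps, kind="stable")
        assert (np.diff(np.asarray(q)[order]) >= -1e-12).all()
        perm = np.random.default_rng(0).permutation(len(ps))
        q_perm = bh_fdr(np.asarray(ps)[perm])
        assert np.allclose(np.asarray(q_perm), np.asarray(q)[perm])


class TestSpearman:
    def test_monotone_and_hand_example(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert spearman_rho(x, x).effect == 1.0
        assert spearman_rho(x, [-v for v in x]).effect == -1.0
        # 1 - 6*sum(d^2)/(n(n^2-1)) with d = (1,-1,1,-1): 1 - 24/60
        assert spearman_rho(x, [2, 1, 4, 3]).effect == pytest.approx(0.6)

    def test_constant_input_flagged(self):
        res = spearman_rho([1, 1, 1], [1, 2, 3])
        assert "constant_input" in res.flags


class TestBootstrapSpearman:
    def test_perfect_monotone_interval(self):
        pairs = [(i, i * 2.0) for i in range(10)]
        assert bootstrap_spearman_ci(pairs, n_boot=200, seed=1) == (1.0, 1.0)

    def test_seed_determinism(self):
        rng = np.random.default_rng(5)
        pairs = np.column_stack([rng.normal(size=30), rng.normal(size=30)])
        ci1 = bootstrap_spearman_ci(pairs, n_boot=300, seed=42)
        ci2 = bootstrap_spearman_ci(pairs, n_boot=300, seed=42)
        assert ci1 == ci2

    def test_constant_data_raises(self):
        with pytest.raises(ValueError):
            bootstrap_spearman_ci([(1, 1)] * 5, n_boot=50, seed=0)


class TestPercentileRank:
    def test_full_tie_is_median(self):
        out = percentile_rank({g: 7 for g in "abcd"}, list("abcd"))
        assert all(v == pytest.approx(50.0) for v in out.values())

    def test_formula_by_hand(self):
        out = percentile_rank({"a": 0, "b": 1, "c": 2, "d": 3}, list("abcd"))
        assert [out[g] for g in "abcd"] == pytest.approx([12.5, 37.5, 62.5, 87.5])

    def test_missing_gene_counts_as_zero(self):
        out = percentile_rank({"a": 5}, ["a", "b"])
        assert out["b"] < out["a"]

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            percentile_rank({"a": 1}, [])
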