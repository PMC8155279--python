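"""Oracle and property tests for the shared statistical machinery."""

from itertools import permutations

import numpy as np
import pytest
from scipy import stats as sps

from pdmci.exceptions import DegenerateDesignError, ValidationError
from pdmci.stats_core import (bh_fdr, pairwise_posthoc, partial_spearman,
                              permutation_group_test, rank_group_tests)

from conftest import covariate_block


def bh_bruteforce(p):
    """Independent O(m^2) step-up implementation used as the oracle."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    for rank_pos, i in enumerate(order, start=1):
        candidates = []
        for k in range(rank_pos, m + 1):
            candidates.append(p[order[k - 1]] * m / k)
        adj[i] = min(1.0, min(candidates))
    return adj


class TestBhFdr:
    @pytest.mark.parametrize("p, expected", [
        ((0.01, 0.02, 0.04, 0.05), (0.04, 0.04, 0.05, 0.05)),
        ((1.0,), (1.0,)),
        ((0.3,), (0.3,)),
    ])
    def test_worked_examples(self, p, expected):
        assert np.allclose(bh_fdr(p), expected)

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.uniform(size=int(rng.integers(1, 25)))
            assert np.allclose(bh_fdr(p), bh_bruteforce(p))

    @pytest.mark.parametrize("bad", [[], [1.2], [-0.1], [np.nan]])
    def test_rejects_invalid_input(self, bad):
        with pytest.raises(ValidationError):
            bh_fdr(bad)


def anova_f(y, g):
    """Textbook one-way ANOVA F, the enumeration oracle's statistic."""
    groups = [y[g == k] for k in np.unique(g)]
    grand = y.mean()
    ssb = sum(len(x) * (x.mean() - grand) ** 2 for x in groups)
    ssw = sum(((x - x.mean()) ** 2).sum() for x in groups)
    df1 = len(groups) - 1
    df2 = len(y) - len(groups)
    return (ssb / df1) / (ssw / df2)


class TestPermutationGroupTest:
    def test_exhaustive_matches_relabeling_enumeration(self):
        """For small n without covariates the permutation distribution is
        the full set of group relabelings; the p-value must equal the
        enumerated exceedance fraction of the classic ANOVA F."""
        y = np.array([1.2, 0.3, -0.5, 2.0, 0.9, -1.1])
        g = np.array([0, 0, 0, 1, 1, 1])
        res = permutation_group_test(y, g, n_perm=100_000, seed=0)
        obs = anova_f(y, g)
        count = sum(anova_f(y[list(p)], g) >= obs - 1e-12
                    for p in permutations(range(6)))
        assert res.n_perm_used == 720
        assert res.p_raw == pytest.approx(count / 720)
        assert res.statistic == pytest.approx(obs)

    def test_constant_response_gives_null_result(self):
        res = permutation_group_test(np.ones(20), np.repeat([0, 1], 10),
                                     n_perm=200, seed=1)
        assert res.statistic == 0.0
        assert res.p_raw == 1.0

    def test_saturated_effect_reaches_minimum_p(self):
        rng = np.random.default_rng(2)
        y = np.concatenate([rng.normal(0, 1, 40), rng.normal(3, 1, 40)])
        g = np.repeat([0, 1], 40)
        res = permutation_group_test(y, g, n_perm=500, seed=3)
        assert res.p_raw == pytest.approx(1 / 501)

    def test_small_group_raises_degenerate_design(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=12)
        g = np.array([0] * 10 + [1] * 2)
        cov = rng.normal(size=(12, 3))
        with pytest.raises(DegenerateDesignError):
            permutation_group_test(y, g, cov, n_perm=100, seed=0)

    def test_seeded_runs_are_bit_identical(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=(40, 3))
        g = np.repeat([0, 1], 20)
        cov = covariate_block(rng, 40)
        a = permutation_group_test(y, g, cov, n_perm=300, seed=11)
        b = permutation_group_test(y, g, cov, n_perm=300, seed=11)
        assert a.statistic == b.statistic and a.p_raw == b.p_raw

    def test_multivariate_reduces_to_anova_for_d1(self):
        """The Pillai pseudo-F with d = 1 and no covariates must equal the
        classic ANOVA F."""
        rng = np.random.default_rng(5)
        y = rng.normal(size=30)
        g = np.repeat([0, 1, 2], 10)
        res = permutation_group_test(y, g, n_perm=100, seed=0)
        assert res.statistic == pytest.approx(anova_f(y, g))


class TestPairwisePosthoc:
    def test_four_groups_give_six_adjusted_results(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=48)
        g = np.repeat(list("abcd"), 12)
        out = pairwise_posthoc(y, g, n_perm=200, seed=0)
        assert len(out) == 6
        assert all(r.p_fdr is not None for r in out)

    def test_deviant_group_drives_its_three_pairs(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=60)
        g = np.repeat(list("abcd"), 15)
        y[g == "d"] += 4.0
        out = pairwise_posthoc(y, g, n_perm=400, seed=1)
        with_d = [r.p_fdr for r in out if "d" in r.label]
        without_d = [r.p_fdr for r in out if "d" not in r.label]
        assert max(with_d) < 0.05
        assert min(without_d) > 0.05

    def test_empty_pair_list_rejected(self):
        with pytest.raises(ValidationError):
            pairwise_posthoc(np.arange(8.0), np.repeat([0, 1], 4), pairs=[])


class TestPartialSpearman:
    def test_reduces_to_plain_spearman_without_covariates(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        pc = partial_spearman(x, y)
        rho, p = sps.spearmanr(x, y)
        assert pc.rho == pytest.approx(rho)
        assert pc.p_raw == pytest.approx(p, rel=0.05)

    def test_perfect_monotone_association(self):
        x = np.arange(10.0)
        assert partial_spearman(x, x**3).rho == pytest.approx(1.0)

    @pytest.mark.parametrize("fx", [np.exp, np.cbrt, lambda v: 5 * v - 2])
    def test_invariant_to_monotone_transforms(self, fx):
        rng = np.random.default_rng(9)
        x = rng.normal(size=35)
        y = 0.5 * x + rng.normal(size=35)
        cov = covariate_block(rng, 35)
        base = partial_spearman(x, y, cov)
        trans = partial_spearman(fx(x), fx(y), cov)
        assert trans.rho == pytest.approx(base.rho)

    def test_shared_confounder_is_removed(self):
        rng = np.random.default_rng(10)
        c = rng.normal(size=400)
        x = c + 0.4 * rng.normal(size=400)
        y = c + 0.4 * rng.normal(size=400)
        raw = partial_spearman(x, y)
        part = partial_spearman(x, y, c)
        assert raw.rho > 0.7
        assert abs(part.rho) < 0.15

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateDesignError):
            partial_spearman(np.ones(10), np.arange(10.0))


class TestRankGroupTests:
    def test_extreme_separation_matches_scipy_u(self):
        omnibus, posthocs = rank_group_tests(
            np.array([1, 2, 3, 4, 5, 6.0]), np.repeat(["a", "b"], 3))
        u, p = sps.mannwhitneyu([1, 2, 3], [4, 5, 6],
                                alternative="two-sided")
        assert posthocs[0].statistic == pytest.approx(u)
        assert posthocs[0].p_raw == pytest.approx(p)
        assert u == 0.0

    def test_all_tied_values(self):
        omnibus, posthocs = rank_group_tests(np.ones(12),
                                             np.repeat(list("abc"), 4))
        assert omnibus.statistic == 0.0
        assert omnibus.p_raw == 1.0

    def test_kruskal_matches_scipy(self):
        rng = np.random.default_rng(11)
        v = rng.normal(size=30)
        g = np.repeat(list("abc"), 10)
        omnibus, _ = rank_group_tests(v, g)
        h, p = sps.kruskal(v[:10], v[10:20], v[20:])
        assert omnibus.statistic == pytest.approx(h)
        assert omnibus.p_raw == pytest.approx(p)
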