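"""Gated statistics: descriptives, gates, exact tests, multiplicity."""

import itertools

import numpy as np
import pytest

from mieeg.cohort_stats import (
    between_compare,
    bonferroni,
    chi_square,
    describe,
    neglog_p_map,
    normality_gate,
    paired_compare,
    variance_gate,
)

KVIQ_CONTROL = [85, 84, 86, 82, 87]
KVIQ_EXPERIMENTAL = [84, 86, 89, 83, 85, 83]


class TestDescribe:
    def test_kviq_control(self):
        d = describe(KVIQ_CONTROL)
        assert round(d["mean"], 2) == 84.8
        assert round(d["sd"], 2) == 1.92

    def test_kviq_experimental(self):
        d = describe(KVIQ_EXPERIMENTAL)
        assert round(d["mean"], 2) == 85.0
        assert round(d["sd"], 2) == 2.28

    def test_constant_values(self):
        d = describe([3.0, 3.0, 3.0])
        assert d["sd"] == 0.0 and d["median"] == 3.0

    def test_single_value_errors(self):
        with pytest.raises(ValueError):
            describe([1.0])


class TestGates:
    def test_normal_sample_mostly_passes(self):
        rng = np.random.default_rng(0)
        passes = sum(
            normality_gate(rng.standard_normal(50))[0] == "normal" for _ in range(200)
        )
        assert 0.85 <= passes / 200 <= 1.0

    def test_exponential_sample_mostly_fails(self):
        rng = np.random.default_rng(1)
        fails = sum(
            normality_gate(rng.exponential(size=50))[0] == "non-normal"
            for _ in range(200)
        )
        assert fails / 200 > 0.8

    def test_too_small_sample_errors(self):
        with pytest.raises(ValueError):
            normality_gate([1.0, 2.0])

    def test_equal_variances_mostly_pass(self):
        rng = np.random.default_rng(2)
        passes = sum(
            variance_gate(rng.standard_normal(30), rng.standard_normal(30))[0]
            == "homogeneous"
            for _ in range(200)
        )
        assert 0.85 <= passes / 200 <= 1.0

    def test_very_unequal_variances_fail(self):
        rng = np.random.default_rng(3)
        fails = sum(
            variance_gate(rng.normal(0, 5, 30), rng.normal(0, 1, 30))[0]
            == "heterogeneous"
            for _ in range(100)
        )
        assert fails / 100 > 0.9

    def test_identical_groups_homogeneous(self):
        g = [1.0, 2.0, 3.0]
        assert variance_gate(g, g)[0] == "homogeneous"


def brute_force_wilcoxon_p(diffs):
    """Exact two-sided signed-rank p by enumerating all sign patterns."""
    d = np.asarray(diffs, dtype=float)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    n = len(d)
    total = ranks.sum()
    stats = []
    for signs in itertools.product([0, 1], repeat=n):
        stats.append(sum(r for r, s in zip(ranks, signs) if s))
    stats = np.array(stats)
    w_min = min(w_obs, total - w_obs)
    p = np.mean(np.minimum(stats, total - stats) <= w_min)
    return p


def brute_force_mannwhitney_p(g1, g2):
    """Exact two-sided U-test p by enumerating group assignments."""
    pooled = np.concatenate([g1, g2])
    n1 = len(g1)

    def u_stat(idx):
        a = pooled[list(idx)]
        b = np.delete(pooled, list(idx))
        return sum((x > y) + 0.5 * (x == y) for x in a for y in b)

    u_obs = u_stat(range(n1))
    n2 = len(g2)
    mid = n1 * n2 / 2.0
    us = [u_stat(c) for c in itertools.combinations(range(n1 + n2), n1)]
    return np.mean([abs(u - mid) >= abs(u_obs - mid) - 1e-12 for u in us])


class TestPairedCompare:
    def test_identical_is_degenerate(self):
        res = paired_compare([1, 2, 3], [1, 2, 3])
        assert res.degenerate and res.p == 1.0

    def test_all_positive_n6_wilcoxon_exact(self):
        # non-normal differences force the signed-rank branch
        pre = np.zeros(6)
        post = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 1000.0])
        res = paired_compare(pre, post)
        assert res.test == "wilcoxon signed-rank"
        assert res.p == pytest.approx(2 / 64)
        assert res.p == pytest.approx(brute_force_wilcoxon_p(post - pre))

    def test_t_branch_matches_closed_form(self):
        pre = np.array([10.0, 11.0, 12.0])
        post = pre + np.array([1.0, 2.0, 3.0])
        res = paired_compare(pre, post)
        assert res.test == "paired t"
        # t = mean(d) / (sd(d)/sqrt(n)) with d = [1,2,3]
        assert abs(res.statistic) == pytest.approx(2.0 / (1.0 / np.sqrt(3.0)))

    def test_exact_small_sample_matches_enumeration(self, rng):
        for _ in range(10):
            d = rng.choice([-8, -4, -2, -1, 1, 2, 4, 8], size=7, replace=False)
            pre = np.zeros(7)
            post = d.astype(float)
            res = paired_compare(pre, post)
            if res.test == "wilcoxon signed-rank":
                assert res.p == pytest.approx(brute_force_wilcoxon_p(d), abs=1e-12)


class TestBetweenCompare:
    def test_extreme_two_two_split(self):
        res = between_compare([1.0, 2.0], [3.0, 4.0])
        assert res.test == "mann-whitney u"
        assert res.p == pytest.approx(1 / 3)
        assert res.p == pytest.approx(brute_force_mannwhitney_p([1, 2], [3, 4]))

    def test_identical_groups_p_one(self):
        res = between_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p > 0.9

    def test_shifted_normals_high_power(self):
        rng = np.random.default_rng(4)
        rejections = sum(
            between_compare(rng.standard_normal(30), rng.standard_normal(30) + 2.0).p
            < 0.05
            for _ in range(100)
        )
        assert rejections / 100 > 0.95

    def test_exact_branch_matches_enumeration(self, rng):
        for _ in range(10):
            vals = rng.choice(np.arange(1, 40, dtype=float), size=8, replace=False)
            g1, g2 = vals[:4], vals[4:]
            res = between_compare(g1, g2)
            if res.test == "mann-whitney u":
                assert res.p == pytest.approx(
                    brute_force_mannwhitney_p(g1, g2), abs=1e-12
                )


class TestChiSquare:
    def test_sex_table_value_and_warning(self):
        res = chi_square([[4, 1], [6, 0]])
        assert res.statistic == pytest.approx(1.32)
        assert res.warnings  # small expected counts flagged

    def test_proportional_table_zero(self):
        res = chi_square([[10, 10], [5, 5]])
        assert res.statistic == pytest.approx(0.0)

    def test_perfect_association(self):
        res = chi_square([[10, 0], [0, 10]])
        assert res.statistic == pytest.approx(20.0)

    def test_fisher_variant(self):
        res = chi_square([[4, 1], [6, 0]], fisher=True)
        assert res.test == "fisher exact"
        assert 0 < res.p <= 1

    def test_zero_marginal_errors(self):
        with pytest.raises(ValueError):
            chi_square([[0, 0], [3, 4]])


class TestBonferroni:
    @pytest.mark.parametrize(
        "ps,expected",
        [([0.01], [0.01]), ([0.02, 0.03], [0.04, 0.06]), ([0.9, 0.9], [1.0, 1.0])],
    )
    def test_adjustment(self, ps, expected):
        assert np.allclose(bonferroni(ps), expected)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.5])


class TestNeglogMap:
    def test_closed_form_values(self):
        rng = np.random.default_rng(5)
        pre = {"a": rng.standard_normal(8)}
        post = {"a": pre["a"] + 0.0}
        out = neglog_p_map(pre, {"a": pre["a"].copy()})
        assert out["a"]["neglog_p"] == pytest.approx(0.0)  # p = 1 -> 0
        post = {"a": pre["a"] + 5.0}
        out = neglog_p_map(pre, post)
        assert out["a"]["neglog_p"] > 1.3  # p < 0.05
        assert out["a"]["significant"]

    def test_region_mismatch_errors(self):
        with pytest.raises(ValueError):
            neglog_p_map({"a": np.ones(3)}, {"b": np.ones(3)})


def test_test_selection_is_reproducible(rng):
    pre = rng.standard_normal(10)
    post = pre + rng.standard_normal(10) * 0.5
    a = paired_compare(pre, post)
    b = paired_compare(pre, post)
    assert (a.test, a.statistic, a.p) == (b.test, b.statistic, b.p)
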