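from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from avipref.community import (
    anosim,
    bray_curtis,
    compact_letters,
    kruskal_wallis,
    one_way_anova,
    pairwise_contrasts,
    spearman_rho,
)


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        d = bray_curtis(np.array([[1.0, 2, 3], [1, 2, 3]]), transform="none")
        assert d.iloc[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        d = bray_curtis(np.array([[5.0, 0], [0, 9.0]]), transform="none")
        assert d.iloc[0, 1] == 1.0

    def test_hand_value(self):
        d = bray_curtis(np.array([[1.0, 3], [3, 1.0]]), transform="none")
        assert d.iloc[0, 1] == pytest.approx(0.5)

    def test_sqrt_transform_applied(self):
        x = np.array([[4.0, 0], [1.0, 0]])
        d = bray_curtis(x, transform="sqrt")
        assert d.iloc[0, 1] == pytest.approx(1 / 3)  # |2-1|/(2+1)

    def test_metric_properties(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 20, size=(6, 8)).astype(float)
        d = bray_curtis(x)
        arr = d.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 0)
        assert ((arr >= 0) & (arr <= 1)).all()

    def test_all_zero_rows_defined_as_zero(self):
        d = bray_curtis(np.array([[0.0, 0], [0, 0.0]]), transform="none")
        assert d.iloc[0, 1] == 0.0

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            bray_curtis(np.array([[1.0, -1], [0, 2.0]]))


def exhaustive_anosim_p(d, n_per_group):
    """Oracle: exact permutation distribution over all distinct labelings."""
    n = d.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    ranks = stats.rankdata(d[iu, ju])
    m = ranks.size

    def r_stat(labels):
        within = labels[iu] == labels[ju]
        return (ranks[~within].mean() - ranks[within].mean()) / (m / 2)

    obs = r_stat(np.array([0] * n_per_group + [1] * (n - n_per_group)))
    rs = []
    for combo in combinations(range(n), n_per_group):
        labels = np.ones(n, dtype=int)
        labels[list(combo)] = 0
        rs.append(r_stat(labels))
    rs = np.array(rs)
    return obs, float((rs >= obs - 1e-12).mean())


class TestAnosim:
    def make_separated(self, gap=10.0):
        rng = np.random.default_rng(1)
        a = rng.random((4, 5))
        b = rng.random((4, 5)) + gap
        return np.vstack([a, b]), ["g1"] * 4 + ["g2"] * 4

    def test_perfect_separation_r_one(self):
        x, groups = self.make_separated()
        res = anosim(bray_curtis(x, transform="none"), groups, n_perm=199, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p <= 0.05

    def test_r_bounded(self):
        rng = np.random.default_rng(2)
        res = anosim(
            bray_curtis(rng.random((8, 4))), ["a", "a", "a", "a", "b", "b", "b", "b"],
            n_perm=99, seed=0,
        )
        assert -1.0 <= res.r <= 1.0
        assert res.p >= 1 / 100

    def test_null_mean_r_near_zero(self):
        # random labels on structureless dissimilarities: E[R] ~ 0
        rng = np.random.default_rng(3)
        rs = []
        for _ in range(200):
            d = bray_curtis(rng.random((8, 5)), transform="none")
            groups = rng.permutation(["a"] * 4 + ["b"] * 4)
            rs.append(anosim(d, groups, n_perm=0, seed=0, pairwise=False).r)
        assert abs(np.mean(rs)) < 0.05

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        x = rng.random((8, 6)) + np.array([0.0] * 4 + [0.6] * 4)[:, None]
        d = bray_curtis(x, transform="none")
        res = anosim(d, ["a"] * 4 + ["b"] * 4, n_perm=999, seed=12)
        obs, p_exact = exhaustive_anosim_p(d.to_numpy(), 4)
        assert res.r == pytest.approx(obs)
        tol = 3 * np.sqrt(p_exact * (1 - p_exact) / 999) + 2 / 999
        assert abs(res.p - p_exact) <= tol

    def test_matches_scikit_bio(self):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import anosim as sk_anosim

        rng = np.random.default_rng(5)
        x = rng.random((9, 5)) * 10
        d = bray_curtis(x)
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        ours = anosim(d, groups, n_perm=99, seed=1)
        theirs = sk_anosim(
            DistanceMatrix(d.to_numpy(), ids=[str(i) for i in range(9)]),
            grouping=groups, permutations=99,
        )
        assert ours.r == pytest.approx(float(theirs["test statistic"]), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        x = rng.random((8, 5))
        groups = ["a"] * 4 + ["b"] * 4
        d = bray_curtis(x)
        d2 = d ** 3  # strictly monotone on [0, 1]
        r1 = anosim(d, groups, n_perm=0, pairwise=False).r
        r2 = anosim(d2, groups, n_perm=0, pairwise=False).r
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_pairwise_bonferroni_alpha(self):
        rng = np.random.default_rng(8)
        x = rng.random((9, 4))
        res = anosim(bray_curtis(x), ["a"] * 3 + ["b"] * 3 + ["c"] * 3, n_perm=99, seed=0)
        assert res.pairwise["alpha_adj"].iloc[0] == pytest.approx(0.05 / 3)
        assert len(res.pairwise) == 3

    def test_rejects_singleton_group_and_constant_d(self):
        d = bray_curtis(np.random.default_rng(0).random((5, 3)))
        with pytest.raises(ValueError, match="at least two members"):
            anosim(d, ["a", "a", "a", "a", "b"])
        const = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValueError, match="constant"):
            anosim(const, ["a", "a", "b", "b"])

    def test_seed_reproducible(self):
        rng = np.random.default_rng(9)
        d = bray_curtis(rng.random((8, 5)))
        groups = ["a"] * 4 + ["b"] * 4
        p1 = anosim(d, groups, n_perm=199, seed=42).p
        p2 = anosim(d, groups, n_perm=199, seed=42).p
        assert p1 == p2


class TestAnova:
    def test_equal_means_small_f(self):
        rng = np.random.default_rng(0)
        values = np.concatenate([rng.normal(0, 1, 30) for _ in range(3)])
        groups = np.repeat(["a", "b", "c"], 30)
        f, df1, df2, p = one_way_anova(values, groups)
        assert df1 == 2 and df2 == 87
        assert p > 0.001

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 12), rng.normal(1, 1, 15)
        f, _, _, p_f = one_way_anova(np.concatenate([a, b]), ["a"] * 12 + ["b"] * 15)
        t, p_t = stats.ttest_ind(a, b)
        assert f == pytest.approx(t**2, rel=1e-10)
        assert p_f == pytest.approx(p_t, rel=1e-10)

    def test_hand_computed_table(self):
        # brute-force sums of squares for a 3x3 layout
        data = {"a": [1.0, 2, 3], "b": [2.0, 3, 4], "c": [6.0, 7, 8]}
        values = np.concatenate(list(data.values()))
        groups = np.repeat(list(data), 3)
        grand = values.mean()
        ssb = sum(3 * (np.mean(v) - grand) ** 2 for v in data.values())
        ssw = sum(((np.asarray(v) - np.mean(v)) ** 2).sum() for v in data.values())
        f_hand = (ssb / 2) / (ssw / 6)
        f, df1, df2, _ = one_way_anova(values, groups)
        assert (df1, df2) == (2, 6)
        assert f == pytest.approx(f_hand, rel=1e-12)

    def test_zero_within_variance_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([1.0, 1, 2, 2], ["a", "a", "b", "b"])


class TestKruskal:
    def test_uniform_p_under_null(self):
        rng = np.random.default_rng(10)
        ps = []
        for _ in range(400):
            values = rng.normal(size=24)
            h, df, p = kruskal_wallis(values, np.repeat(["a", "b", "c"], 8))
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_fully_ordered_groups_maximal_h(self):
        # no overlap between groups: H equals the value of the fully
        # separated rank configuration, computed by brute force
        values = np.array([1.0, 2, 3, 11, 12, 13, 21, 22, 23])
        groups = np.repeat(["a", "b", "c"], 3)
        h, df, p = kruskal_wallis(values, groups)
        n = 9
        ranks = [np.array([1.0, 2, 3]), np.array([4.0, 5, 6]), np.array([7.0, 8, 9])]
        h_hand = 12 / (n * (n + 1)) * sum(3 * r.mean() ** 2 for r in ranks) - 3 * (n + 1)
        assert h == pytest.approx(h_hand, rel=1e-12)
        assert df == 2

    def test_two_group_decision_matches_mannwhitney(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 10), rng.normal(2, 1, 10)
        _, _, p_kw = kruskal_wallis(np.concatenate([a, b]), ["a"] * 10 + ["b"] * 10)
        p_mw = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        assert (p_kw < 0.05) == (p_mw < 0.05)

    def test_all_tied_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([5.0] * 6, ["a"] * 3 + ["b"] * 3)


class TestContrasts:
    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=30)
        out = pairwise_contrasts(values, np.repeat(["a", "b", "c"], 10))
        assert not out["significant"].any()
        assert set(out.attrs["letters"].values()) == {"A"}

    @pytest.mark.parametrize("method", ["tukey", "rank"])
    def test_one_shifted_group_detected(self, method):
        rng = np.random.default_rng(1)
        low = rng.normal(0, 1, 12)
        med = rng.normal(0, 1, 12)
        high = rng.normal(10, 1, 12)  # +10 sigma
        values = np.concatenate([low, med, high])
        groups = np.repeat(["low", "medium", "high"], 12)
        out = pairwise_contrasts(values, groups, method=method)
        sig = {frozenset((r.group_1, r.group_2)) for r in out.itertuples() if r.significant}
        assert sig == {frozenset(("low", "high")), frozenset(("medium", "high"))}
        letters = out.attrs["letters"]
        assert letters["low"] == letters["medium"] != letters["high"]

    def test_rejects_tiny_groups(self):
        with pytest.raises(ValueError):
            pairwise_contrasts([1.0, 2, 3], ["a", "b", "c"])


class TestCompactLetters:
    def test_table_pattern_low_medium_a_high_b(self):
        letters = compact_letters(
            ["low", "medium", "high"],
            [("low", "high"), ("medium", "high")],
        )
        assert letters == {"low": "A", "medium": "A", "high": "B"}

    def test_all_different(self):
        letters = compact_letters(["a", "b"], [("a", "b")])
        assert letters["a"] != letters["b"]


class TestSpearman:
    def test_monotone_extremes(self):
        rho, _ = spearman_rho([1, 2, 3, 4], [10, 20, 25, 90], n_perm=200, seed=0)
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_rho([1, 2, 3, 4], [4, 3, 2, 1], n_perm=200, seed=0)
        assert rho == pytest.approx(-1.0)

    def test_tied_example_matches_scipy(self):
        x = [1.0, 2, 2, 3, 5, 5, 7]
        y = [3.0, 1, 4, 4, 6, 8, 8]
        rho, _ = spearman_rho(x, y, n_perm=100, seed=0)
        assert rho == pytest.approx(float(stats.spearmanr(x, y).statistic), rel=1e-12)

    def test_permutation_p_detects_strong_association(self):
        rng = np.random.default_rng(2)
        x = np.arange(20.0)
        y = x + rng.normal(0, 1, 20)
        rho, p = spearman_rho(x, y, n_perm=2000, seed=3)
        assert p < 0.01

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1.0, 1, 1, 1], [1.0, 2, 3, 4])
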