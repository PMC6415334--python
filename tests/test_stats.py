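"""Rank statistics against hand computations and scipy oracles."""

import numpy as np
import pytest
import scipy.stats as sps

from falsesignal import CountMatrix
from falsesignal.stats import (
    adjust,
    auroc,
    auroc_matrix,
    denormalize_counts,
    kruskal_matrix,
    kruskal_wallis,
    log2_cpm,
    mann_whitney_u,
    max_abs_log2fc,
    mwu_matrix,
    spearman_all_pairs,
)
from falsesignal.types import PValueSet


class TestLog2CPM:
    def test_hand_values(self, make_matrix):
        X = make_matrix([[1], [3]])
        L = log2_cpm(X)
        assert L.scale == "log2cpm"
        np.testing.assert_allclose(
            L.values[:, 0], [np.log2(2.5e5 + 1), np.log2(7.5e5 + 1)]
        )

    def test_zero_libsize_names_cell(self, make_matrix):
        X = make_matrix([[1, 0], [2, 0]])
        with pytest.raises(ValueError, match="c1"):
            log2_cpm(X)

    def test_roundtrip_recovers_counts(self, make_matrix):
        rng = np.random.default_rng(3)
        X = make_matrix(rng.poisson(4, size=(30, 20)) + (np.arange(20) == 0))
        lib = X.libsizes()
        back = denormalize_counts(log2_cpm(X), lib)
        np.testing.assert_array_equal(back.values, X.values)

    def test_monotone_within_cell(self, make_matrix):
        X = make_matrix([[5, 1], [2, 8], [9, 3]])
        L = log2_cpm(X)
        for j in range(2):
            assert np.array_equal(
                np.argsort(L.values[:, j]), np.argsort(X.values[:, j])
            )


class TestSpearman:
    def test_matches_scipy_on_random_matrix(self, make_matrix):
        rng = np.random.default_rng(0)
        X = make_matrix(rng.poisson(5, size=(20, 30)))
        res = spearman_all_pairs(X)
        rho_ref = sps.spearmanr(X.values.T).statistic
        ok = res.tested_genes
        np.testing.assert_allclose(
            res.rho[np.ix_(ok, ok)], rho_ref[np.ix_(ok, ok)], atol=1e-12
        )

    def test_hand_pair(self, make_matrix):
        X = make_matrix([[1, 2, 3, 4, 5], [5, 6, 7, 8, 7]])
        res = spearman_all_pairs(X)
        ref = sps.spearmanr([1, 2, 3, 4, 5], [5, 6, 7, 8, 7]).statistic
        assert res.rho[0, 1] == pytest.approx(ref, abs=1e-12)
        assert res.rho[0, 1] == pytest.approx(0.8207, abs=5e-4)
        assert res.rho[0, 0] == pytest.approx(1.0)

    def test_family_size_counts_pairs(self, make_matrix):
        rng = np.random.default_rng(1)
        X = make_matrix(rng.poisson(5, size=(40, 10)))
        res = spearman_all_pairs(X)
        assert res.pvals.m == 40 * 39 // 2

    def test_constant_gene_excluded(self, make_matrix):
        rng = np.random.default_rng(2)
        V = rng.poisson(5, size=(5, 12))
        V[2] = 7
        res = spearman_all_pairs(make_matrix(V))
        assert not res.tested_genes[2]
        assert res.pvals.m == 4 * 3 // 2
        assert np.isnan(res.rho[2, 0])


class TestMannWhitney:
    def test_exact_no_overlap(self):
        # C(6,3)=20 arrangements, the observed split is one of the 2 extremes
        _, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_identical_groups(self):
        _, p = mann_whitney_u([2, 2, 2], [2, 2, 2])
        assert p == 1.0

    def test_auc_identity(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(1, 1, 30), rng.normal(0, 1, 25)
        U, _ = mann_whitney_u(x, y)
        vals = np.concatenate([x, y])
        labels = np.array([True] * 30 + [False] * 25)
        assert auroc(vals, labels) == pytest.approx(U / (30 * 25))

    def test_matrix_matches_scipy_with_ties(self):
        rng = np.random.default_rng(5)
        V = rng.poisson(2, size=(40, 36)).astype(float)
        ma = np.arange(36) < 16
        U, p = mwu_matrix(V, ma, ~ma)
        for g in range(40):
            if np.ptp(V[g]) == 0:
                assert p[g] == 1.0
                continue
            ref = sps.mannwhitneyu(
                V[g, ma], V[g, ~ma], alternative="two-sided", method="asymptotic"
            )
            assert U[g] == pytest.approx(ref.statistic)
            assert p[g] == pytest.approx(ref.pvalue, abs=1e-12)


class TestKruskalWallis:
    def test_matches_scipy(self):
        rng = np.random.default_rng(6)
        V = rng.poisson(3, size=(30, 45)).astype(float)
        groups = np.repeat([0, 1, 2], 15)
        H, p = kruskal_matrix(V, groups)
        for g in range(30):
            if np.ptp(V[g]) == 0:
                assert H[g] == 0 and p[g] == 1.0
                continue
            ref = sps.kruskal(*[V[g, groups == k] for k in range(3)])
            assert H[g] == pytest.approx(ref.statistic)
            assert p[g] == pytest.approx(ref.pvalue)

    def test_two_groups_agrees_with_mwu(self):
        # KW with 2 groups is the MWU without continuity correction
        rng = np.random.default_rng(7)
        x, y = rng.poisson(5, 40).astype(float), rng.poisson(6, 35).astype(float)
        _, p_kw = kruskal_wallis(np.concatenate([x, y]), np.array([0] * 40 + [1] * 35))
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        assert p_kw == pytest.approx(res.pvalue, rel=1e-6)

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(8)
        V = rng.negative_binomial(2, 0.3, size=(400, 60)).astype(float)
        groups = np.repeat([0, 1, 2], 20)
        _, p = kruskal_matrix(V, groups)
        # ranks are discrete so only a coarse KS check is meaningful
        assert sps.kstest(p, "uniform").statistic < 0.1

    def test_constant_values(self):
        H, p = kruskal_wallis(np.ones(9), np.repeat([0, 1, 2], 3))
        assert H == 0.0 and p == 1.0

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            kruskal_wallis(np.arange(4.0), np.array([0, 0, 0, 0]))


class TestAdjust:
    def test_bonferroni_hand_case(self):
        out = adjust(np.array([0.01]), "bonferroni", m=5)
        assert out.adjusted[0] == pytest.approx(0.05)

    def test_bh_step_up_hand_case(self):
        out = adjust(np.array([0.01, 0.02, 0.03, 0.04]), "bh")
        np.testing.assert_allclose(out.adjusted, [0.04, 0.04, 0.04, 0.04])

    def test_single_test_either_method(self):
        for method in ("bonferroni", "bh"):
            out = adjust(np.array([0.3]), method)
            assert out.adjusted[0] == pytest.approx(0.3)

    def test_bh_preserves_ordering(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=50)
        out = adjust(p, "bh")
        order = np.argsort(p)
        assert np.all(np.diff(out.adjusted[order]) >= -1e-12)
        assert np.all(out.adjusted >= p)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            adjust(np.array([1.2]), "bonferroni")
        with pytest.raises(ValueError):
            PValueSet(raw=np.array([-0.1]), m=1)


class TestAUC:
    def test_perfect_separation(self):
        assert auroc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_all_tied(self):
        assert auroc([3, 3, 3, 3], [0, 0, 1, 1]) == 0.5

    def test_shuffled_labels_centre_on_half(self):
        rng = np.random.default_rng(10)
        vals = rng.normal(size=200)
        aucs = []
        for _ in range(200):
            labels = rng.permutation(np.array([True] * 100 + [False] * 100))
            aucs.append(auroc(vals, labels))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.01)

    def test_matrix_agrees_with_scalar(self):
        rng = np.random.default_rng(11)
        V = rng.poisson(3, size=(10, 30)).astype(float)
        labels = np.arange(30) < 12
        out = auroc_matrix(V, labels)
        for g in range(10):
            assert out[g] == pytest.approx(auroc(V[g], labels))


class TestEffectSize:
    def test_two_groups(self, make_matrix):
        L = make_matrix([[2, 2, 5, 5]], scale="log2cpm")
        out = max_abs_log2fc(L, np.array(["a", "a", "b", "b"]))
        assert out[0] == pytest.approx(3.0)

    def test_three_groups_max_over_pairs(self, make_matrix):
        L = make_matrix([[1, 2, 6]], scale="log2cpm")
        out = max_abs_log2fc(L, np.array(["a", "b", "c"]))
        assert out[0] == pytest.approx(5.0)

    def test_identical_means(self, make_matrix):
        L = make_matrix([[3, 3, 3, 3]], scale="log2cpm")
        out = max_abs_log2fc(L, np.array(["a", "a", "b", "b"]))
        assert out[0] == 0.0
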