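"""Negative-control protocol: classification rules, filtering, permutation."""

import numpy as np
import pandas as pd
import pytest

from falsesignal import CountMatrix
from falsesignal.controls import (
    bias_direction_summary,
    build_permutation_null,
    classify_correlations,
    count_de_false_positives,
    filter_cells_genes,
    select_similar_pair,
)
from falsesignal.stats import adjust, log2_cpm, spearman_all_pairs
from falsesignal.types import PValueSet, SimTruth


def _truth(is_de, direction):
    is_de = np.asarray(is_de, dtype=bool)
    return SimTruth(
        is_de=is_de,
        direction=direction,
        fold=np.where(is_de, 10.0, 1.0),
        group_labels=np.array(["A", "B"], dtype=object),
    )


def _fake_spearman(rho_01, n_genes=3):
    """A SpearmanResult-like screen where only pair (0,1) is significant."""
    from falsesignal.stats import SpearmanResult

    rho = np.eye(n_genes)
    rho[0, 1] = rho[1, 0] = rho_01
    pair_i, pair_j = np.triu_indices(n_genes, k=1)
    raw = np.where((pair_i == 0) & (pair_j == 1), 1e-9, 0.9)
    pvals = adjust(PValueSet(raw=raw, m=len(raw)), "bonferroni")
    return SpearmanResult(
        rho=rho, pvals=pvals, pair_i=pair_i, pair_j=pair_j,
        tested_genes=np.ones(n_genes, dtype=bool),
        genes=np.array([f"g{i}" for i in range(n_genes)], dtype=object),
    )


class TestClassifyCorrelations:
    def test_concordant_de_pair_is_tp(self):
        res = _fake_spearman(0.9)
        rep = classify_correlations(res, _truth([1, 1, 0], [1, 1, 0]))
        assert rep.n_tp == 1 and rep.n_fp == 0

    def test_pair_with_non_de_gene_is_fp(self):
        res = _fake_spearman(0.9)
        rep = classify_correlations(res, _truth([1, 0, 0], [1, 0, 0]))
        assert rep.n_fp == 1 and rep.n_tp == 0

    def test_opposite_direction_positive_rho_is_fp(self):
        res = _fake_spearman(0.9)
        rep = classify_correlations(res, _truth([1, 1, 0], [1, -1, 0]))
        assert rep.n_fp == 1 and rep.n_tp == 0

    def test_opposite_direction_negative_rho_is_tp(self):
        res = _fake_spearman(-0.9)
        rep = classify_correlations(res, _truth([1, 1, 0], [1, -1, 0]))
        assert rep.n_tp == 1 and rep.n_fp == 0

    def test_requires_bonferroni(self):
        res = _fake_spearman(0.9)
        res.pvals = PValueSet(raw=res.pvals.raw, m=res.pvals.m)
        with pytest.raises(ValueError):
            classify_correlations(res, _truth([1, 1, 0], [1, 1, 0]))


class TestFiltering:
    def _matrix(self, type_counts, n_genes=40, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.concatenate(
            [[t] * c for t, c in type_counts.items()]
        ).astype(object)
        n = len(labels)
        V = rng.poisson(5, size=(n_genes, n))
        V[:, 0] += 1  # guard against a zero-libsize cell
        return CountMatrix(
            values=V, genes=[f"g{i}" for i in range(n_genes)],
            cells=[f"c{i}" for i in range(n)], labels=labels,
        )

    def test_rare_type_removed(self):
        X = self._matrix({"A": 60, "B": 36, "C": 4})
        out = filter_cells_genes(X)
        assert set(np.unique(out.labels)) == {"A", "B"}
        assert out.n_cells == 96

    def test_rarely_detected_gene_removed(self):
        X = self._matrix({"A": 60, "B": 36, "C": 4})
        X.values[5] = 0
        X.values[5, :3] = 1  # detected in 3 of 96 surviving cells (3.1% < 5%)
        out = filter_cells_genes(X)
        assert "g5" not in out.genes

    def test_all_types_kept_when_common(self):
        X = self._matrix({"A": 50, "B": 30, "C": 20})
        out = filter_cells_genes(X)
        assert out.n_cells == 100

    def test_fewer_than_two_types_errors(self):
        X = self._matrix({"A": 98, "B": 2})
        with pytest.raises(ValueError):
            filter_cells_genes(X)


class TestPairSelection:
    def test_two_types_forced(self, make_matrix):
        X = make_matrix(np.random.default_rng(0).poisson(5, (10, 20)) + 1,
                        labels=np.array(["A"] * 10 + ["B"] * 10, dtype=object))
        assert select_similar_pair(X) == ("A", "B")

    def test_closest_mean_profiles_win(self, make_matrix):
        # types A and B nearly identical; C has a reshuffled profile
        rng = np.random.default_rng(1)
        base = rng.poisson(np.arange(1, 16)[:, None], (15, 10)) + 1
        V = np.hstack([base, base + 1, base[::-1]])
        X = make_matrix(V, labels=np.array(
            ["A"] * 10 + ["B"] * 10 + ["C"] * 10, dtype=object))
        assert select_similar_pair(X) == ("A", "B")

    def test_equidistant_tie_breaks_lexicographically(self, make_matrix):
        # B and C are mirror images of A: d(A,B) == d(A,C) < d(B,C)
        a = np.full((4, 5), 8.0)
        V = np.hstack([a, a * 2, a / 2])
        X = make_matrix(V.astype(int), labels=np.array(
            ["A"] * 5 + ["B"] * 5 + ["C"] * 5, dtype=object))
        pair = select_similar_pair(X)
        assert pair == ("A", "B")


@pytest.fixture(scope="module")
def null_case(small_grouped):
    X = filter_cells_genes(small_grouped.counts)
    return X, build_permutation_null(X, seed=3)


class TestPermutationNull:
    def test_multiset_preserved_per_gene(self, null_case):
        # the permutation itself must exactly preserve each gene's multiset
        # of log2-CPM values over the pair's cells (de-normalization to
        # integer counts afterwards only adds bounded rounding error)
        X, null = null_case
        Lb = log2_cpm(null.before).values[:, null.pair_cell_idx]
        for g in np.flatnonzero(null.permuted_mask):
            np.testing.assert_array_equal(
                np.sort(Lb[g]), np.sort(null.permuted_log[g])
            )

    def test_untouched_outside_pair_and_below_threshold(self, null_case):
        X, null = null_case
        pc = np.isin(X.labels, null.pair)
        np.testing.assert_array_equal(
            null.after.values[:, ~pc], null.before.values[:, ~pc]
        )
        kept = ~null.permuted_mask
        np.testing.assert_array_equal(
            null.after.values[kept], null.before.values[kept]
        )

    def test_libsizes_approximately_preserved(self, null_case):
        # de-normalizing with each cell's own library size keeps sizes
        # centred on the originals; per-cell deviation reflects only the
        # permuted genes' contribution differences plus rounding
        X, null = null_case
        before, after = null.before.libsizes(), null.after.libsizes()
        assert abs(after.mean() - before.mean()) / before.mean() < 0.01
        assert np.all(np.abs(after - before) / before < 0.15)

    def test_same_seed_same_permutation_different_seed_same_genes(self, null_case):
        X, null = null_case
        again = build_permutation_null(X, seed=3)
        other = build_permutation_null(X, seed=4)
        np.testing.assert_array_equal(null.after.values, again.after.values)
        np.testing.assert_array_equal(null.permuted_mask, other.permuted_mask)
        assert not np.array_equal(null.after.values, other.after.values)

    def test_null_types_permute_most_genes(self, make_matrix):
        # two identical distributions: ~80% of genes expected above p=0.2
        rng = np.random.default_rng(8)
        V = rng.negative_binomial(2, 0.2, size=(400, 160))
        X = make_matrix(V, labels=np.array(["A"] * 80 + ["B"] * 80, dtype=object))
        null = build_permutation_null(X, seed=0)
        frac = null.permuted_mask.mean()
        assert 0.7 < frac < 0.9

    def test_strong_de_gene_not_permuted(self, make_matrix):
        rng = np.random.default_rng(9)
        V = rng.poisson(20, size=(400, 120))
        V[0, :60] = rng.poisson(200, 60)  # 10-fold in type A, ~2% of libsize
        X = make_matrix(V, labels=np.array(["A"] * 60 + ["B"] * 60, dtype=object))
        null = build_permutation_null(X, seed=0)
        assert not null.permuted_mask[0]


class TestFalsePositiveCount:
    def test_raw_passthrough_rarely_significant(self, small_grouped):
        X = filter_cells_genes(small_grouped.counts)
        null = build_permutation_null(X, seed=5)
        rep = count_de_false_positives(
            null.after, X.labels, null.pair, null.permuted_genes
        )
        assert rep.n_permuted == len(null.permuted_genes)
        assert rep.n_significant <= 1  # Bonferroni expected count ~0.05
        assert rep.fp_fraction == rep.n_significant / rep.n_permuted

    def test_constant_gene_never_significant(self, make_matrix):
        rng = np.random.default_rng(10)
        V = rng.poisson(8, size=(30, 80))
        V[4] = 6  # constant across all cells
        X = make_matrix(V, labels=np.array(["A"] * 40 + ["B"] * 40, dtype=object))
        rep = count_de_false_positives(X, X.labels, ("A", "B"), ["g4"])
        assert rep.n_significant == 0


class TestBiasDirection:
    def test_identity_imputer_all_none(self, small_grouped):
        X = filter_cells_genes(small_grouped.counts)
        null = build_permutation_null(X, seed=6)
        out = bias_direction_summary(
            null.after, null.after, null.permuted_genes, null.pair, X.labels
        )
        assert set(out["direction"]) == {"none"}
        assert np.isnan(out.attrs["concordance"])

    def test_concordance_at_least_half(self, small_grouped):
        from falsesignal.imputers import impute_knn_smooth

        X = filter_cells_genes(small_grouped.counts)
        null = build_permutation_null(X, seed=6)
        smoothed = impute_knn_smooth(null.after, 10)
        out = bias_direction_summary(
            null.after, smoothed, null.permuted_genes, null.pair, X.labels
        )
        assert 0.5 <= out.attrs["concordance"] <= 1.0

    def test_random_perturbation_near_half(self, make_matrix):
        rng = np.random.default_rng(11)
        V = rng.poisson(50, size=(400, 100))
        labels = np.array(["A"] * 50 + ["B"] * 50, dtype=object)
        before = make_matrix(V, labels=labels)
        # independent symmetric per-gene shifts in a random direction
        signs = rng.choice([-1, 1], size=400)
        after_vals = np.clip(V + signs[:, None] * (np.arange(100) < 50) * 5, 0, None)
        after = make_matrix(after_vals, labels=labels)
        out = bias_direction_summary(
            before, after, before.genes, ("A", "B"), labels
        )
        assert out.attrs["concordance"] == pytest.approx(0.5, abs=0.08)
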