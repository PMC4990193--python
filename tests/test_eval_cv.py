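"""Fold partitioning, masking, Pearson accuracy and summary analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gbsimpute.callers import ValidationSet
from gbsimpute.eval_cv import (
    bin_summary,
    estimate_maf,
    fold_accuracies,
    mask_fold,
    median_over_folds,
    partition_validation,
    pca_from_relationship,
    pearson_r,
    relationship_matrix,
)
from gbsimpute.genolik import DosageMatrix


def make_vs(n, n_sites=20, n_ind=50, seed=0):
    rng = np.random.default_rng(seed)
    coords = rng.choice(n_sites * n_ind, size=n, replace=False)
    return ValidationSet(coords // n_ind, coords % n_ind,
                         rng.integers(0, 3, size=n).astype(float))


class TestPartition:
    def test_even_split_sizes(self):
        part = partition_validation(make_vs(100), 10, seed=1)
        assert [len(f) for f in part.folds] == [10] * 10

    def test_remainder_spread_within_one(self):
        part = partition_validation(make_vs(103), 10, seed=1)
        sizes = sorted(len(f) for f in part.folds)
        assert sizes == [10] * 7 + [11] * 3

    def test_disjoint_and_exhaustive(self):
        vs = make_vs(137)
        part = partition_validation(vs, 10, seed=3)
        combined = np.concatenate(part.folds)
        assert len(combined) == len(np.unique(combined)) == len(vs)

    def test_same_seed_reproduces_partition(self):
        vs = make_vs(55)
        a = partition_validation(vs, 10, seed=7)
        b = partition_validation(vs, 10, seed=7)
        for fa, fb in zip(a.folds, b.folds):
            np.testing.assert_array_equal(fa, fb)

    def test_too_few_entries_rejected(self):
        with pytest.raises(ValueError):
            partition_validation(make_vs(5), 10, seed=0)


class TestMaskFold:
    def test_masks_exactly_the_fold_coordinates(self):
        d = DosageMatrix(np.ones((20, 50)))
        vs = make_vs(40)
        part = partition_validation(vs, 4, seed=2)
        masked = mask_fold(d, vs, part.folds[0])
        assert int(np.isnan(masked.values).sum()) == len(part.folds[0])
        si = vs.site_idx[part.folds[0]]
        sj = vs.sample_idx[part.folds[0]]
        assert np.isnan(masked.values[si, sj]).all()
        assert not np.isnan(d.values).any()  # input untouched

    def test_empty_fold_is_identity(self):
        d = DosageMatrix(np.ones((4, 4)))
        vs = make_vs(10, 4, 4)
        masked = mask_fold(d, vs, np.empty(0, dtype=int))
        np.testing.assert_array_equal(masked.values, d.values)

    def test_already_missing_coordinate_raises(self):
        d = DosageMatrix(np.ones((20, 50)))
        vs = make_vs(10)
        d.values[vs.site_idx[0], vs.sample_idx[0]] = np.nan
        with pytest.raises(ValueError, match="already missing"):
            mask_fold(d, vs, np.arange(10))


class TestPearsonR:
    @pytest.mark.parametrize("x,y,want", [
        ((0, 1, 2), (0, 1, 2), 1.0),
        ((0, 1, 2), (2, 1, 0), -1.0),
    ])
    def test_exact_examples(self, x, y, want):
        assert pearson_r(x, y) == pytest.approx(want)

    def test_invariant_vector_undefined(self):
        assert np.isnan(pearson_r((0, 1, 2), (1, 1, 1)))

    def test_short_vector_undefined(self):
        assert np.isnan(pearson_r([1.0], [2.0]))

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            pearson_r([1, 2], [1, 2, 3])

    def test_matches_scipy_two_pass_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            assert pearson_r(x, y) == pytest.approx(
                stats.pearsonr(x, y)[0], abs=1e-12)


class TestFoldAccuracies:
    def test_single_masked_entry_undefined(self):
        vs = ValidationSet([0], [0], [1.0])
        imputed = DosageMatrix(np.ones((2, 2)))
        recs = fold_accuracies(vs, imputed, np.array([0]), "site")
        assert recs.loc[0, "L"] == 1 and np.isnan(recs.loc[0, "r"])

    def test_perfect_imputation_r_one(self):
        vs = ValidationSet([0, 0, 0], [0, 1, 2], [0.0, 1.0, 2.0])
        imputed = DosageMatrix(np.array([[0.0, 1.0, 2.0]]))
        recs = fold_accuracies(vs, imputed, np.arange(3), "site")
        assert recs.loc[0, "r"] == pytest.approx(1.0)

    def test_random_imputation_r_near_zero(self):
        rng = np.random.default_rng(9)
        L = 400
        obs = rng.integers(0, 3, size=L).astype(float)
        vs = ValidationSet(np.zeros(L, dtype=int), np.arange(L), obs)
        imputed = DosageMatrix(rng.permutation(obs)[None, :])
        recs = fold_accuracies(vs, imputed, np.arange(L), "site")
        assert abs(recs.loc[0, "r"]) < 3 / np.sqrt(L)

    def test_per_individual_grouping(self):
        vs = ValidationSet([0, 1, 0, 1], [0, 0, 1, 1], [0.0, 2.0, 1.0, 1.0])
        imputed = DosageMatrix(np.array([[0.1, 0.9], [1.9, 1.1]]))
        recs = fold_accuracies(vs, imputed, np.arange(4), "individual")
        assert list(recs["unit"]) == [0, 1] and list(recs["L"]) == [2, 2]


class TestMedianOverFolds:
    def test_median_of_defined_r(self):
        recs = pd.DataFrame({"unit": [1, 1, 1], "fold": [0, 1, 2],
                             "L": [40, 40, 40], "r": [0.5, 0.9, 0.7]})
        out = median_over_folds(recs, min_L=30)
        assert out.loc[0, "median_r"] == pytest.approx(0.7)

    def test_small_L_records_excluded_at_site_level(self):
        recs = pd.DataFrame({"unit": [1, 1], "fold": [0, 1],
                             "L": [40, 10], "r": [0.5, 0.9]})
        out = median_over_folds(recs, min_L=30)
        assert out.loc[0, "median_r"] == pytest.approx(0.5)
        assert out.attrs["n_excluded_small_L"] == 1
        out_all = median_over_folds(recs, min_L=0)
        assert out_all.loc[0, "median_r"] == pytest.approx(0.7)

    def test_all_undefined_unit_reported_not_dropped(self):
        recs = pd.DataFrame({"unit": [3, 3], "fold": [0, 1],
                             "L": [40, 40], "r": [np.nan, np.nan]})
        out = median_over_folds(recs, min_L=30)
        assert len(out) == 1 and np.isnan(out.loc[0, "median_r"])
        assert out.attrs["n_units_all_undefined"] == 1


class TestSiteSummaries:
    def test_maf_examples(self):
        d = DosageMatrix(np.array([[0.0, 0.0, 2.0],
                                   [2.0, 2.0, 2.0],
                                   [1.0, 1.0, np.nan]]))
        maf = estimate_maf(d)
        np.testing.assert_allclose(maf, [1 / 3, 0.0, 0.5])

    def test_all_missing_site_is_nan(self):
        maf = estimate_maf(DosageMatrix(np.full((1, 3), np.nan)))
        assert np.isnan(maf[0])

    def test_bin_edges_left_open_right_closed(self):
        x = np.array([0.0, 0.1, 0.1000001, 0.5])
        acc = np.array([1.0, 2.0, 3.0, 4.0])
        out = bin_summary(x, acc, n_bins=5, hi=0.5)
        assert out.loc[0, "n"] == 1  # 0.1 in (0, 0.1]; 0.0 outside
        assert out.loc[1, "n"] == 1 and out.loc[4, "n"] == 1
        np.testing.assert_allclose(out["bin_right"],
                                   [0.1, 0.2, 0.3, 0.4, 0.5])

    def test_bin_means_match_groupby_oracle(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(0.001, 1.0, size=200)
        acc = rng.normal(size=200)
        out = bin_summary(x, acc, n_bins=4, hi=1.0)
        oracle = pd.DataFrame({"b": np.ceil(x / 0.25) - 1, "a": acc}) \
            .groupby("b")["a"].agg(["mean", "median"])
        for b in range(4):
            assert out.loc[b, "mean"] == pytest.approx(oracle.loc[b, "mean"])
            assert out.loc[b, "median"] == pytest.approx(oracle.loc[b, "median"])

    def test_empty_bins_reported_with_nan(self):
        out = bin_summary(np.array([0.05]), np.array([1.0]), n_bins=5, hi=0.5)
        assert out.loc[0, "n"] == 1 and out.loc[4, "n"] == 0
        assert np.isnan(out.loc[4, "mean"])


def vanraden_bruteforce(dosages):
    """Direct double-loop evaluation of the VanRaden relationship matrix."""
    filled = dosages.copy()
    for i in range(filled.shape[0]):
        m = np.nanmean(filled[i])
        filled[i, np.isnan(filled[i])] = m
    p = filled.mean(axis=1) / 2.0
    denom = 2.0 * sum(pk * (1 - pk) for pk in p)
    n_ind = filled.shape[1]
    A = np.zeros((n_ind, n_ind))
    for a in range(n_ind):
        for b in range(n_ind):
            A[a, b] = sum((filled[k, a] - 2 * p[k]) * (filled[k, b] - 2 * p[k])
                          for k in range(filled.shape[0])) / denom
    return A


class TestRelationshipMatrix:
    def test_matches_bruteforce_on_toy_matrix(self):
        rng = np.random.default_rng(13)
        d = rng.integers(0, 3, size=(5, 4)).astype(float)
        d[0, 1] = np.nan
        np.testing.assert_allclose(relationship_matrix(d),
                                   vanraden_bruteforce(d), atol=1e-10)

    def test_duplicate_homozygous_individuals(self):
        d = np.array([[0.0, 0.0, 2.0],
                      [2.0, 2.0, 0.0],
                      [0.0, 0.0, 2.0],
                      [2.0, 2.0, 2.0]])
        A = relationship_matrix(d)
        assert A[0, 1] == pytest.approx(A[0, 0])

    def test_symmetric_with_nonnegative_diagonal(self):
        rng = np.random.default_rng(14)
        d = rng.integers(0, 3, size=(30, 12)).astype(float)
        A = relationship_matrix(d)
        np.testing.assert_allclose(A, A.T, atol=1e-12)
        assert (np.diag(A) >= 0).all()

    def test_high_missingness_sites_excluded(self):
        d = np.array([[0.0, np.nan, np.nan, np.nan],  # 75% missing: dropped
                      [0.0, 1.0, 2.0, 1.0],
                      [2.0, 1.0, 0.0, 1.0]])
        A_filtered = relationship_matrix(d, max_missing=0.5)
        A_direct = relationship_matrix(d[1:], max_missing=1.0)
        np.testing.assert_allclose(A_filtered, A_direct, atol=1e-12)


class TestPcaFromRelationship:
    def test_reproduces_top_eigenpair(self):
        rng = np.random.default_rng(15)
        M = rng.normal(size=(4, 4))
        A = M @ M.T
        scores = pca_from_relationship(A, n_components=2)
        w, v = np.linalg.eigh(A)
        want = v[:, -1] * np.sqrt(w[-1])
        if want[np.argmax(np.abs(want))] < 0:
            want = -want
        np.testing.assert_allclose(scores[:, 0], want, atol=1e-10)

    def test_rank_one_matrix_single_component(self):
        u = np.array([1.0, -2.0, 0.5])
        A = np.outer(u, u)
        scores = pca_from_relationship(A, n_components=2)
        assert np.linalg.norm(scores[:, 1]) == pytest.approx(0.0, abs=1e-6)

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            pca_from_relationship(np.array([[1.0, 2.0], [0.0, 1.0]]))
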