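import numpy as np
import pandas as pd
import pytest

from medipdmr import (DMR, DmrCallParams, FeatureMatrix, call_dmrs, dendrogram,
                      dmr_feature_matrix, lda_train_predict, pca, tmm_factors)
from medipdmr import test_windows as window_tests
from medipdmr.model import NormalizationFactors, WindowCounts


def make_counts(matrix, samples=None):
    matrix = np.asarray(matrix, dtype=np.int64)
    n = matrix.shape[0]
    samples = samples or [f"s{j+1}" for j in range(matrix.shape[1])]
    return WindowCounts(
        window_size=1000, chroms=np.full(n, "c1", dtype=object),
        starts=np.arange(n, dtype=np.int64) * 1000,
        ends=(np.arange(n, dtype=np.int64) + 1) * 1000,
        samples=samples, counts=matrix,
        library_sizes=matrix.sum(axis=0).astype(float))


def unit_norm(counts):
    return NormalizationFactors(samples=list(counts.samples),
                                factors=np.ones(len(counts.samples)),
                                library_sizes=counts.library_sizes)


def dmr(start, end):
    return DMR(name=f"d{start}", chrom="c1", start=start, end=end, n_windows=1,
               n_sig_windows=1, min_p=1e-5, fdr_q=0.01, log2_fold_change=1.0)


def feature_matrix(values, samples=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{j+1}" for j in range(values.shape[0])]
    windows = pd.DataFrame({"chrom": "c1",
                            "start": np.arange(values.shape[1]) * 1000,
                            "end": (np.arange(values.shape[1]) + 1) * 1000})
    return FeatureMatrix(samples=samples, values=values, windows=windows)


class TestFeatureMatrix:
    def test_columns_are_dmr_windows(self):
        rng = np.random.default_rng(1)
        counts = make_counts(rng.poisson(50, size=(20, 4)))
        dmrs = [dmr(0, 2000), dmr(5000, 7000), dmr(10_000, 11_000)]
        fm = dmr_feature_matrix(counts, unit_norm(counts), dmrs)
        assert len(fm.windows) == 5
        assert fm.values.shape == (4, 5)

    def test_cpm_invariance_under_depth(self):
        """Doubling counts and library size leaves a sample's row unchanged."""
        base = np.full((10, 2), 50)
        base[:, 1] *= 2
        counts = make_counts(base)
        fm = dmr_feature_matrix(counts, unit_norm(counts), [dmr(0, 5000)])
        assert np.allclose(fm.values[0], fm.values[1])

    def test_zero_count_maps_to_zero(self):
        counts = make_counts([[0, 5], [3, 2]])
        fm = dmr_feature_matrix(counts, unit_norm(counts), [dmr(0, 1000)])
        assert fm.values[0, 0] == 0.0

    def test_empty_dmr_set_rejected(self):
        counts = make_counts([[1, 2]])
        with pytest.raises(ValueError, match="empty DMR"):
            dmr_feature_matrix(counts, unit_norm(counts), [])


class TestPca:
    def test_separates_planted_groups(self, small_dataset):
        counts, _, sheet = small_dataset
        results, norm, _ = window_tests(counts, sheet["group"])
        dmrs = call_dmrs(results, DmrCallParams())
        fm = dmr_feature_matrix(counts, norm, dmrs)
        scores, _ = pca(fm, 2)
        case = scores[:6, 0]
        control = scores[6:, 0]
        assert case.max() < control.min() or control.max() < case.min()

    def test_duplicated_samples_identical_scores(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(6, 10))
        x[3] = x[0]
        scores, _ = pca(feature_matrix(x), 2)
        assert np.allclose(scores[0], scores[3])

    def test_explained_variance_sums_to_one(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(8, 5))
        _, evr = pca(feature_matrix(x), 5)
        assert evr.sum() <= 1 + 1e-9
        assert evr.sum() == pytest.approx(1.0, abs=1e-9)

    def test_scores_invariant_to_sample_order(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(7, 12))
        scores, _ = pca(feature_matrix(x), 3)
        perm = rng.permutation(7)
        scores_p, _ = pca(feature_matrix(x[perm]), 3)
        assert np.allclose(scores_p, scores[perm])

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError, match="n_components"):
            pca(feature_matrix(np.eye(3)), 3)


class TestDendrogram:
    def test_two_samples_single_merge(self):
        nwk = dendrogram(feature_matrix([[0.0, 0.0], [3.0, 4.0]], ["a", "b"]))
        assert nwk == "(a:5,b:5);"  # merge at their Euclidean distance 5

    def test_identical_pair_merges_first(self):
        x = [[0.0, 0.0], [0.0, 0.0], [9.0, 9.0]]
        nwk = dendrogram(feature_matrix(x, ["a", "b", "c"]))
        assert "(a:0,b:0)" in nwk

    def test_leaf_set_is_sample_set(self, small_dataset):
        counts, _, sheet = small_dataset
        results, norm, _ = window_tests(counts, sheet["group"])
        dmrs = call_dmrs(results)
        fm = dmr_feature_matrix(counts, norm, dmrs)
        nwk = dendrogram(fm)
        for s in fm.samples:
            assert s in nwk


class TestLda:
    def _separable(self, seed=5, n=10, shift=4.0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(2 * n, 30))
        x[:n, :5] += shift
        labels = ["case"] * n + ["control"] * n
        return feature_matrix(x), labels

    def test_separable_data_high_loo(self):
        fm, labels = self._separable()
        _, loo = lda_train_predict(fm, labels)
        assert loo >= 0.9

    def test_test_sample_equal_to_training_case(self):
        fm, labels = self._separable()
        test = feature_matrix(fm.values[:1])
        preds, _ = lda_train_predict(fm, labels, test)
        assert preds == ["case"]

    def test_one_class_rejected(self):
        fm, _ = self._separable()
        with pytest.raises(ValueError, match="two classes"):
            lda_train_predict(fm, ["case"] * len(fm.samples))

    def test_column_mismatch_rejected(self):
        fm, labels = self._separable()
        bad = feature_matrix(fm.values[:2, :10])
        with pytest.raises(ValueError, match="column"):
            lda_train_predict(fm, labels, bad)

    def test_affine_rescaling_invariance(self):
        """Uniform feature rescaling applied to train and test together
        leaves predictions unchanged."""
        fm, labels = self._separable()
        test = feature_matrix(fm.values[[0, -1]] + 0.01)
        preds, loo = lda_train_predict(fm, labels, test)
        scaled_train = feature_matrix(fm.values * 3.0 + 7.0)
        scaled_test = feature_matrix((test.values * 3.0) + 7.0)
        preds_s, loo_s = lda_train_predict(scaled_train, labels, scaled_test)
        assert preds == preds_s
        assert loo == pytest.approx(loo_s)

    def test_permuted_labels_near_chance(self):
        """Shuffling labels on structureless data gives chance-level LOO."""
        rng = np.random.default_rng(6)
        x = rng.normal(size=(20, 40))
        fm = feature_matrix(x)
        accs = []
        for seed in range(10):
            perm_rng = np.random.default_rng(seed)
            labels = ["case"] * 10 + ["control"] * 10
            perm_rng.shuffle(labels)
            _, loo = lda_train_predict(fm, labels)
            accs.append(loo)
        assert 0.2 <= np.mean(accs) <= 0.8
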