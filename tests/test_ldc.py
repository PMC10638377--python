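"""LDC scorer tests: clustering, a−b scores, normalization, histograms."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

import ldclean as L
from ldclean.ldc import ScoringError, contributor_raw_scores

from conftest import oracle_tensor


def binary_rows(p1):
    p1 = np.asarray(p1, dtype=float)
    return np.column_stack([1 - p1, p1])


class TestFitLabelClusters:
    def test_onehot_fixed_point(self):
        probs = np.eye(3)[[0, 0, 1, 1, 2, 2]]
        cc = L.fit_label_clusters(probs, [0, 0, 1, 1, 2, 2])
        np.testing.assert_allclose(cc.centroids, np.eye(3), atol=1e-9)
        assert not cc.degenerate

    def test_two_group_means(self):
        # {0.1, 0.2, 0.8, 0.9} splits into clusters with means 0.15 and 0.85
        cc = L.fit_label_clusters(binary_rows([0.1, 0.2, 0.8, 0.9]), [0, 0, 1, 1])
        np.testing.assert_allclose(sorted(cc.centroids[:, 1]), [0.15, 0.85])

    def test_identical_rows_degenerate(self):
        probs = np.tile([0.5, 0.5], (4, 1))
        cc = L.fit_label_clusters(probs, [0, 1, 0, 1])
        assert cc.degenerate
        np.testing.assert_allclose(cc.centroids[0], cc.centroids[1])

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            L.fit_label_clusters(np.eye(3)[:2], [0, 1])

    def test_matches_exhaustive_wcss_minimum(self):
        # global optimality on random tiny binary instances
        from itertools import product

        rng = np.random.default_rng(0)
        for _ in range(150):
            n = rng.integers(2, 11)
            probs = binary_rows(rng.random(n))
            labels = rng.integers(0, 2, n)
            cc = L.fit_label_clusters(probs, labels)
            d = cdist(probs, cc.centroids)
            fitted = (d.min(axis=1) ** 2).sum()
            best = np.inf
            for assign in product([0, 1], repeat=int(n)):
                a = np.array(assign)
                if a.sum() in (0, n):
                    continue
                w = sum(
                    ((probs[a == g] - probs[a == g].mean(axis=0)) ** 2).sum()
                    for g in (0, 1)
                )
                best = min(best, w)
            assert fitted <= best + 1e-9

    def test_agrees_with_sklearn_kmeans_multiclass(self):
        # independent cross-check of the C>2 Lloyd path
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(1)
        raw = rng.dirichlet([0.4, 0.4, 0.4], size=90)
        labels = raw.argmax(axis=1)
        cc = L.fit_label_clusters(raw, labels)
        km = KMeans(n_clusters=3, n_init=20, random_state=0).fit(raw)
        ours = (cdist(raw, cc.centroids).min(axis=1) ** 2).sum()
        theirs = (cdist(raw, km.cluster_centers_).min(axis=1) ** 2).sum()
        assert ours <= theirs * 1.001

    def test_class_mandate_is_bijection(self):
        rng = np.random.default_rng(2)
        probs = rng.dirichlet([1, 1, 1, 1], size=40)
        cc = L.fit_label_clusters(probs, rng.integers(0, 4, 40))
        assert sorted(cc.class_of_centroid) == [0, 1, 2, 3]


class TestRawNoiseScore:
    def test_at_own_centroid(self):
        own = np.array([1.0, 0.0])
        other = np.array([[0.0, 1.0]])
        d = np.linalg.norm(own - other[0])
        assert L.raw_noise_score(own, own, other) == pytest.approx(-d)

    def test_equidistant_zero(self):
        row = np.array([0.5, 0.5])
        assert L.raw_noise_score(
            row, np.array([0.9, 0.1]), np.array([[0.1, 0.9]])
        ) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # sample labeled class 0 at (0.3, 0.7); a=0.7071, b=0.1414
        score = L.raw_noise_score(
            np.array([0.3, 0.7]), np.array([0.8, 0.2]), np.array([[0.2, 0.8]])
        )
        assert score == pytest.approx(0.5657, abs=1e-4)

    def test_multiclass_uses_nearest_other_centroid(self):
        row = np.array([0.1, 0.8, 0.1])
        centroids = np.array([[0.8, 0.1, 0.1], [0.1, 0.8, 0.1], [0.2, 0.2, 0.6]])
        cc = L.ClassCentroids(centroids=centroids,
                              class_of_centroid=np.arange(3))
        scores = contributor_raw_scores(row[None, :], [0], cc)
        b = min(np.linalg.norm(row - centroids[1]), np.linalg.norm(row - centroids[2]))
        a = np.linalg.norm(row - centroids[0])
        assert scores[0] == pytest.approx(a - b)


class TestAggregateAndNormalize:
    def test_minmax_arithmetic(self):
        t = L.aggregate_and_normalize(np.array([[-1.0, 0.0, 1.0]]))
        np.testing.assert_allclose(t.normalized, [0.0, 50.0, 100.0])
        assert not t.degenerate

    def test_all_equal_degenerate(self):
        t = L.aggregate_and_normalize(np.array([[2.0, 2.0, 2.0]]))
        np.testing.assert_allclose(t.normalized, [50.0, 50.0, 50.0])
        assert t.degenerate

    def test_mean_before_normalize(self):
        # two contributors disagree symmetrically: means tie, so both get 50;
        # normalize-then-mean would *also* give 50 here, so add a third sample
        # breaking the symmetry to pin the order of operations
        raw = np.array([[0.0, 2.0, 5.0], [2.0, 0.0, 5.0]])
        t = L.aggregate_and_normalize(raw)
        np.testing.assert_allclose(t.mean_raw, [1.0, 1.0, 5.0])
        np.testing.assert_allclose(t.normalized, [0.0, 0.0, 100.0])

    def test_ordering_preserved(self):
        rng = np.random.default_rng(3)
        raw = rng.standard_normal((4, 30))
        t = L.aggregate_and_normalize(raw)
        np.testing.assert_array_equal(
            np.argsort(t.mean_raw, kind="stable"),
            np.argsort(t.normalized, kind="stable"),
        )

    def test_extrema_attained(self):
        rng = np.random.default_rng(4)
        t = L.aggregate_and_normalize(rng.standard_normal((3, 50)))
        assert t.normalized.min() == 0.0
        assert t.normalized.max() == 100.0


class TestLdcScores:
    def test_oracle_tensor_ranks_flips_top(self, small_flipped_dataset):
        ds = small_flipped_dataset
        table = L.ldc_scores(oracle_tensor(ds), ds)
        flipped = ds.flip_mask
        assert table.normalized[flipped].min() > table.normalized[~flipped].max()

    def test_correctly_sided_samples_below_midpoint(self):
        p1 = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        labels = (p1 > 0.5).astype(int)
        ds = L.LabeledDataset(features=np.zeros((6, 1)), observed_labels=labels,
                              n_classes=2)
        tensor = L.PredictionTensor(contributors=[(0, 0)],
                                    probs=binary_rows(p1)[None])
        table = L.ldc_scores(tensor, ds)
        assert np.all(table.mean_raw < 0)  # a < b on the correct side

    def test_permutation_equivariance(self, small_flipped_dataset):
        ds = small_flipped_dataset
        tensor = oracle_tensor(ds, jitter=0.2, seed=5)
        table = L.ldc_scores(tensor, ds)
        perm = np.random.default_rng(6).permutation(ds.n_samples)
        ds_p = ds.subset(perm)
        tensor_p = L.PredictionTensor(contributors=tensor.contributors,
                                      probs=tensor.probs[:, perm, :])
        table_p = L.ldc_scores(tensor_p, ds_p)
        np.testing.assert_allclose(
            table_p.normalized, table.normalized[perm], atol=1e-9
        )

    def test_binary_class_symmetry(self, small_flipped_dataset):
        # relabeling 0<->1 and mirroring probability rows leaves scores unchanged
        ds = small_flipped_dataset
        tensor = oracle_tensor(ds, jitter=0.3, seed=7)
        table = L.ldc_scores(tensor, ds)
        ds_m = L.LabeledDataset(
            features=ds.features, observed_labels=1 - ds.observed_labels,
            sample_ids=ds.sample_ids, true_labels=1 - ds.true_labels, n_classes=2,
        )
        tensor_m = L.PredictionTensor(contributors=tensor.contributors,
                                      probs=tensor.probs[:, :, ::-1])
        table_m = L.ldc_scores(tensor_m, ds_m)
        np.testing.assert_allclose(table_m.normalized, table.normalized, atol=1e-9)

    def test_all_degenerate_raises(self):
        ds = L.LabeledDataset(features=np.zeros((4, 1)),
                              observed_labels=[0, 1, 0, 1], n_classes=2)
        flat = np.tile([0.5, 0.5], (4, 1))[None]
        with pytest.raises(ScoringError):
            L.ldc_scores(L.PredictionTensor(contributors=[(0, 0)], probs=flat), ds)


class TestSingleModelLdc:
    def test_exact_scored_count_and_exclusion(self, small_flipped_dataset):
        ds = small_flipped_dataset
        spec = L.ModelSpec(hidden_sizes=[8], epochs=3, seed=1)
        table = L.single_model_ldc(spec, ds, val_fraction=0.2, seed=2)
        assert len(table.sample_ids) == 160
        assert len(table.unscored_ids) == 40
        assert len(np.intersect1d(table.sample_ids, table.unscored_ids)) == 0

    def test_degenerate_split_rejected(self):
        spec_ds = L.SyntheticSpec(n_per_class=[2, 2], n_features=4,
                                  class_separation=5.0, seed=3)
        ds = L.generate_separable(spec_ds)
        with pytest.raises(ValueError):
            L.single_model_ldc(L.ModelSpec(epochs=1), ds, val_fraction=0.9)


class TestScoreHistogram:
    def test_top_edge_in_last_bin(self):
        edges, counts = L.score_histogram(np.array([100.0]), 16)
        assert counts[0][-1] == 1
        assert len(edges) == 17

    def test_right_open_convention(self):
        edges, counts = L.score_histogram(np.array([0.0, 25.0, 50.0, 75.0, 100.0]), 4)
        np.testing.assert_array_equal(counts[0], [1, 1, 1, 2])

    def test_per_group_conservation(self, small_flipped_dataset):
        ds = small_flipped_dataset
        table = L.ldc_scores(oracle_tensor(ds, jitter=0.2, seed=8), ds)
        _, counts = L.score_histogram(table.normalized, 16, ds.observed_labels)
        for g in np.unique(ds.observed_labels):
            assert counts[g].sum() == np.sum(ds.observed_labels == g)

    def test_invalid_bin_count(self):
        with pytest.raises(ValueError):
            L.score_histogram(np.array([1.0]), 1)
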