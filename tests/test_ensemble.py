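"""Ensemble trainer tests: fold plans, best-epoch selection, tensor contracts."""

import numpy as np
import pytest

import ldclean as L
from ldclean.ensemble import EPOCH_METRICS, derive_contributor_seed


def two_gaussian_dataset(n=60, seed=0):
    spec = L.SyntheticSpec(n_per_class=[n, n], n_features=4,
                           class_separation=6.0, seed=seed)
    return L.generate_separable(spec)


class TestKFoldPartition:
    def test_exact_partition(self):
        ds = two_gaussian_dataset(5)
        plan = L.kfold_partition(ds, 5, stratified=False, seed=0)
        sizes = [len(plan.val_positions(i)) for i in range(5)]
        assert sizes == [2, 2, 2, 2, 2]
        all_val = np.concatenate([plan.val_positions(i) for i in range(5)])
        assert sorted(all_val) == list(range(10))

    def test_stratified_fold_class_sizes(self):
        spec = L.SyntheticSpec(n_per_class=[60, 40], n_features=4,
                               class_separation=5.0, seed=1)
        ds = L.generate_separable(spec)
        plan = L.kfold_partition(ds, 5, stratified=True, seed=2)
        for i in range(5):
            labels = ds.observed_labels[plan.val_positions(i)]
            assert np.sum(labels == 0) == 12
            assert np.sum(labels == 1) == 8

    def test_determinism(self):
        ds = two_gaussian_dataset(20)
        a = L.kfold_partition(ds, 4, seed=5)
        b = L.kfold_partition(ds, 4, seed=5)
        np.testing.assert_array_equal(a.fold_of_sample, b.fold_of_sample)

    def test_invalid_k(self):
        ds = two_gaussian_dataset(20)
        with pytest.raises(ValueError):
            L.kfold_partition(ds, 1)

    def test_k_exceeding_class_size(self):
        spec = L.SyntheticSpec(n_per_class=[3, 50], n_features=4,
                               class_separation=5.0, seed=1)
        ds = L.generate_separable(spec)
        with pytest.raises(ValueError):
            L.kfold_partition(ds, 5, stratified=True)


@pytest.fixture(scope="module")
def splits():
    ds = two_gaussian_dataset(40, seed=3)
    plan = L.kfold_partition(ds, 5, seed=3)
    return ds.subset(plan.train_positions(0)), ds.subset(plan.val_positions(0))


class TestTrainAndSelect:
    def test_trace_and_restoration(self, splits):
        train, val = splits
        spec = L.ModelSpec(hidden_sizes=[8], epochs=6, seed=4)
        model, trace = L.train_and_select(spec, train, val, "log_loss")
        assert len(trace.values) == 6
        assert trace.best_epoch == int(np.argmin(trace.values))
        # best epoch improves on the first epoch for separable data
        assert trace.values[trace.best_epoch] <= trace.values[0]

    def test_earliest_tie_wins_for_accuracy(self, splits):
        train, val = splits
        spec = L.ModelSpec(hidden_sizes=[8], epochs=5, seed=5)
        _, trace = L.train_and_select(spec, train, val, "total_accuracy")
        best = max(trace.values)
        assert trace.best_epoch == trace.values.index(best)

    def test_roc_auc_multiclass_rejected(self):
        spec_ds = L.SyntheticSpec(n_per_class=[20, 20, 20], n_features=4,
                                  class_separation=5.0, seed=6)
        ds = L.generate_separable(spec_ds)
        plan = L.kfold_partition(ds, 3, seed=6)
        with pytest.raises(ValueError):
            L.train_and_select(
                L.ModelSpec(epochs=2), ds.subset(plan.train_positions(0)),
                ds.subset(plan.val_positions(0)), "roc_auc",
            )

    def test_unknown_metric_rejected(self, splits):
        train, val = splits
        assert "tangent" not in EPOCH_METRICS
        with pytest.raises(ValueError):
            L.train_and_select(L.ModelSpec(epochs=2), train, val, "tangent_score")


class TestPredictFull:
    def test_simplex_and_determinism(self, small_flipped_dataset):
        ds = small_flipped_dataset
        plan = L.kfold_partition(ds, 4, seed=1)
        spec = L.ModelSpec(hidden_sizes=[8], epochs=3, seed=2)
        model, _ = L.train_and_select(
            spec, ds.subset(plan.train_positions(0)), ds.subset(plan.val_positions(0))
        )
        p1 = L.predict_full(model, ds)
        p2 = L.predict_full(model, ds)
        assert np.allclose(p1.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_array_equal(p1, p2)
        assert p1.shape == (ds.n_samples, ds.n_classes)

    def test_dimension_mismatch(self, small_flipped_dataset):
        ds = small_flipped_dataset
        plan = L.kfold_partition(ds, 4, seed=1)
        model, _ = L.train_and_select(
            L.ModelSpec(hidden_sizes=[4], epochs=2, seed=3),
            ds.subset(plan.train_positions(0)), ds.subset(plan.val_positions(0)),
        )
        with pytest.raises(ValueError):
            model.predict_proba(np.zeros((3, ds.n_features + 1)))


@pytest.fixture(scope="module")
def small_run(small_flipped_dataset):
    ds = small_flipped_dataset
    plan = L.kfold_partition(ds, 5, seed=4)
    specs = [
        L.ModelSpec(hidden_sizes=[8], epochs=3, seed=5),
        L.ModelSpec(architecture="multi_branch_mlp", hidden_sizes=[9, 6],
                    epochs=3, seed=6),
        L.ModelSpec(architecture="conv1d", hidden_sizes=[6], kernel_size=3,
                    conv_channels=2, epochs=3, seed=7),
    ]
    trace_log = []
    tensor = L.build_prediction_tensor(ds, specs, plan, trace_log=trace_log)
    return ds, plan, tensor, trace_log


class TestBuildPredictionTensor:
    def test_contributor_count_and_order(self, small_run):
        _, plan, tensor, _ = small_run
        # 3 architectures x 5 folds = 15 contributors, spec-major ordering
        assert tensor.n_contributors == 15
        assert tensor.contributors == [(m, i) for m in range(3) for i in range(5)]

    def test_covers_all_samples(self, small_run):
        ds, _, tensor, _ = small_run
        assert tensor.probs.shape == (15, ds.n_samples, ds.n_classes)

    def test_trace_log_records_every_contributor(self, small_run):
        _, _, _, trace_log = small_run
        assert len(trace_log) == 15
        assert all(t["metric_name"] == "log_loss" for t in trace_log)

    def test_fold_rotation(self, small_run):
        ds, plan, _, _ = small_run
        served = np.concatenate([plan.val_positions(i) for i in range(plan.k)])
        assert sorted(served) == list(range(ds.n_samples))

    def test_single_spec_five_contributors(self, small_flipped_dataset):
        ds = small_flipped_dataset
        plan = L.kfold_partition(ds, 5, seed=8)
        tensor = L.build_prediction_tensor(
            ds, [L.ModelSpec(hidden_sizes=[6], epochs=2, seed=9)], plan
        )
        assert tensor.n_contributors == 5

    def test_end_to_end_determinism(self, small_flipped_dataset):
        ds = small_flipped_dataset
        plan = L.kfold_partition(ds, 4, seed=10)
        spec = L.ModelSpec(hidden_sizes=[6], epochs=2, seed=11)
        t1 = L.build_prediction_tensor(ds, [spec], plan)
        t2 = L.build_prediction_tensor(ds, [spec], plan)
        assert np.allclose(t1.probs, t2.probs, atol=1e-5)

    def test_contributor_seeds_differ(self):
        seeds = {derive_contributor_seed(3, m, i) for m in range(3) for i in range(5)}
        assert len(seeds) == 15


def test_mean_validation_accuracy_high_on_clean_preset():
    # on the clean separable preset (no flips) contributors reach >=99%
    spec_ds = L.SyntheticSpec(n_per_class=[150, 150], n_features=20,
                              class_separation=6.0, seed=12)
    ds = L.generate_separable(spec_ds)
    plan = L.kfold_partition(ds, 5, seed=12)
    accs = []
    for i in range(5):
        model, trace = L.train_and_select(
            L.ModelSpec(hidden_sizes=[16], epochs=8, seed=13 + i),
            ds.subset(plan.train_positions(i)),
            ds.subset(plan.val_positions(i)),
            "total_accuracy",
        )
        accs.append(max(trace.values))
    assert np.mean(accs) >= 0.99
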