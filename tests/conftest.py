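"""Shared fixtures: small benchmark datasets and oracle prediction tensors."""

import numpy as np
import pytest

import ldclean as L

# The study conditions used by the slower end-to-end tests: the clean
# separable preset (2 x 1000 samples, 20 features, separation 6) with 30%
# of labels flipped, and the default single-branch MLP sizing (150/30).
STUDY_SEED = 1
STUDY_SPEC = L.SyntheticSpec(
    n_per_class=[1000, 1000], n_features=20, class_separation=6.0,
    flip_rate=0.3, seed=STUDY_SEED,
)
STUDY_MODEL = L.ModelSpec(
    architecture="mlp", hidden_sizes=[150, 30], epochs=40,
    learning_rate=0.01, batch_size=32, seed=7,
)


def oracle_tensor(dataset: L.LabeledDataset, n_contributors: int = 1,
                  jitter: float = 0.0, seed: int = 0) -> L.PredictionTensor:
    """Prediction tensor whose rows are (optionally jittered) one-hot truths."""
    onehot = np.eye(dataset.n_classes)[dataset.true_labels]
    rng = np.random.default_rng(seed)
    mats = []
    for _ in range(n_contributors):
        probs = onehot.copy()
        if jitter > 0:
            probs = probs + rng.uniform(0, jitter, probs.shape)
            probs /= probs.sum(axis=1, keepdims=True)
        mats.append(probs)
    contributors = [(0, i) for i in range(n_contributors)]
    return L.PredictionTensor(contributors=contributors, probs=np.stack(mats))


@pytest.fixture(scope="session")
def flipped_dataset() -> L.LabeledDataset:
    """Clean separable preset with 30% tracked label flips."""
    return L.generate_separable(STUDY_SPEC)


@pytest.fixture(scope="session")
def small_flipped_dataset() -> L.LabeledDataset:
    """A fast 2x100 version of the same regime for unit tests."""
    spec = L.SyntheticSpec(
        n_per_class=[100, 100], n_features=8, class_separation=6.0,
        flip_rate=0.2, seed=3,
    )
    return L.generate_separable(spec)


@pytest.fixture(scope="session")
def study_tensor(flipped_dataset) -> L.PredictionTensor:
    """The 1-spec x 5-fold trained ensemble over the flipped study dataset."""
    plan = L.kfold_partition(flipped_dataset, 5, stratified=True, seed=7)
    return L.build_prediction_tensor(flipped_dataset, [STUDY_MODEL], plan)
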