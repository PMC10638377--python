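"""Synthetic benchmark datasets with known, tracked label errors.

Two regimes bracket the difficulty range seen in real record data:

* ``generate_separable`` — well-separated Gaussian class clusters; a clean
  dataset on which a reasonable classifier reaches >99% validation
  accuracy.  Label flips injected afterwards are the *only* errors, so
  error-identification metrics have exact ground truth.
* ``generate_hard`` — overlapping clusters whose Bayes-optimal accuracy is
  ~74%; the errors are inherent ambiguity, not mislabeling, so no flip
  mask exists.

Class mean vectors sit on scaled standard-basis directions so that every
pair of class means is exactly ``class_separation`` apart (in units of the
unit within-class standard deviation); the geometry is deterministic given
the spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .dataset import LabeledDataset


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic class-cluster dataset.

    ``class_separation`` is the pairwise distance between class means in
    units of the (unit) within-class standard deviation.  ``flip_rate`` is
    the per-class fraction of labels to switch; it must stay below 0.5 so
    that flips remain a minority in every class.
    """

    n_per_class: list[int] = field(default_factory=lambda: [1000, 1000])
    n_features: int = 20
    class_separation: float = 6.0
    flip_rate: float = 0.0
    seed: int = 0

    @property
    def n_classes(self) -> int:
        return len(self.n_per_class)

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if any(n <= 0 for n in self.n_per_class):
            raise ValueError("class sizes must be positive")
        if not 0 <= self.flip_rate < 0.5:
            raise ValueError("flip_rate must lie in [0, 0.5)")
        if self.n_features < self.n_classes:
            raise ValueError("n_features must be >= n_classes for the mean layout")
        if self.class_separation < 0:
            raise ValueError("class_separation must be nonnegative")


# Presets for the two difficulty regimes.  The hard preset's separation is
# chosen so the two-Gaussian Bayes accuracy Phi(sep/2) is ~0.74.
CLEAN_PRESET = SyntheticSpec(
    n_per_class=[1000, 1000], n_features=20, class_separation=6.0
)
HARD_PRESET = SyntheticSpec(
    n_per_class=[1000, 1000], n_features=20, class_separation=1.2866
)


def _class_means(spec: SyntheticSpec) -> np.ndarray:
    """(C, d) mean matrix: scaled basis vectors, pairwise distance = separation."""
    means = np.zeros((spec.n_classes, spec.n_features))
    scale = spec.class_separation / np.sqrt(2.0)
    for c in range(spec.n_classes):
        means[c, c] = scale
    return means


def _generate(spec: SyntheticSpec) -> LabeledDataset:
    rng = np.random.default_rng(spec.seed)
    means = _class_means(spec)
    feats, labels = [], []
    for c, n_c in enumerate(spec.n_per_class):
        feats.append(rng.standard_normal((n_c, spec.n_features)) + means[c])
        labels.append(np.full(n_c, c))
    features = np.concatenate(feats)
    observed = np.concatenate(labels)
    ds = LabeledDataset(
        features=features,
        observed_labels=observed,
        true_labels=observed.copy(),
        n_classes=spec.n_classes,
    )
    if spec.flip_rate > 0:
        ds = inject_label_flips(ds, spec.flip_rate, seed=spec.seed + 1)
    return ds


def generate_separable(spec: SyntheticSpec | None = None) -> LabeledDataset:
    """Clean, well-separated class clusters (flips applied if spec.flip_rate > 0)."""
    spec = spec or CLEAN_PRESET
    if spec.class_separation < 4:
        raise ValueError("separable preset expects class_separation >= 4")
    return _generate(spec)


def generate_hard(spec: SyntheticSpec | None = None) -> LabeledDataset:
    """Overlapping clusters: inherent ambiguity rather than mislabeling."""
    spec = spec or HARD_PRESET
    return _generate(spec)


def bayes_accuracy(class_separation: float) -> float:
    """Closed-form Bayes accuracy for two equal-prior unit Gaussians.

    The two-class problem reduces to 1-d along the line joining the means,
    giving accuracy Phi(separation / 2).
    """
    return float(norm.cdf(class_separation / 2.0))


def inject_label_flips(
    dataset: LabeledDataset, flip_rate: float, seed: int = 0
) -> LabeledDataset:
    """Switch exactly ``round(flip_rate * n_c)`` labels per class.

    Flipped samples get a uniformly chosen *different* class as their
    observed label; true labels are preserved and the flip mask records
    which rows changed.  Deterministic given the seed.
    """
    if not 0 <= flip_rate < 0.5:
        raise ValueError("flip_rate must lie in [0, 0.5): flips must stay a minority")
    rng = np.random.default_rng(seed)
    true = (dataset.true_labels if dataset.true_labels is not None
            else dataset.observed_labels).copy()
    observed = true.copy()
    C = dataset.n_classes
    for c in range(C):
        members = np.where(true == c)[0]
        n_flip = int(np.floor(flip_rate * len(members) + 0.5))
        chosen = rng.choice(members, size=n_flip, replace=False)
        # uniform over the C-1 other classes
        offsets = rng.integers(1, C, size=n_flip)
        observed[chosen] = (true[chosen] + offsets) % C
    return LabeledDataset(
        features=dataset.features.copy(),
        observed_labels=observed,
        sample_ids=dataset.sample_ids.copy(),
        true_labels=true,
        n_classes=C,
    )
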