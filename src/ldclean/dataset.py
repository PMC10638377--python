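"""Tabular classification dataset container used throughout the toolkit.

A :class:`LabeledDataset` couples a real-valued feature matrix with the
*observed* integer labels — the labels as they arrived, possibly wrong.
In benchmark mode it additionally carries the hidden *true* labels and the
boolean flip mask marking samples whose observed label was switched, which
is what makes exact error-identification scoring (IoU / EIA) possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class LabeledDataset:
    """Feature matrix plus observed labels, with optional hidden ground truth.

    Parameters
    ----------
    features : (n, d) float array
        One real-valued feature vector per sample.
    observed_labels : (n,) int array
        Class of each sample as labeled, in ``{0..n_classes-1}``.
    sample_ids : (n,) int array, optional
        Stable identifiers; default ``0..n-1``.
    true_labels : (n,) int array, optional
        Hidden ground-truth classes (benchmark mode only).
    flip_mask : (n,) bool array, optional
        True where ``observed_labels != true_labels``.  Derived from
        ``true_labels`` when omitted.
    """

    features: np.ndarray
    observed_labels: np.ndarray
    sample_ids: np.ndarray | None = None
    true_labels: np.ndarray | None = None
    flip_mask: np.ndarray | None = None
    n_classes: int = field(default=0)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-d matrix")
        self.observed_labels = np.asarray(self.observed_labels, dtype=int)
        n = self.features.shape[0]
        if n < 1:
            raise ValueError("dataset must contain at least one sample")
        if self.observed_labels.shape != (n,):
            raise ValueError("observed_labels length must match feature rows")
        if self.sample_ids is None:
            self.sample_ids = np.arange(n)
        else:
            self.sample_ids = np.asarray(self.sample_ids, dtype=int)
            if len(np.unique(self.sample_ids)) != n:
                raise ValueError("sample_ids must be unique")
        if self.n_classes <= 0:
            top = int(self.observed_labels.max())
            if self.true_labels is not None:
                top = max(top, int(np.asarray(self.true_labels).max()))
            self.n_classes = top + 1
        if self.observed_labels.min() < 0 or self.observed_labels.max() >= self.n_classes:
            raise ValueError("observed labels out of range")
        if self.true_labels is not None:
            self.true_labels = np.asarray(self.true_labels, dtype=int)
            if self.true_labels.shape != (n,):
                raise ValueError("true_labels length must match feature rows")
            derived = self.observed_labels != self.true_labels
            if self.flip_mask is None:
                self.flip_mask = derived
            else:
                self.flip_mask = np.asarray(self.flip_mask, dtype=bool)
                if not np.array_equal(self.flip_mask, derived):
                    raise ValueError(
                        "flip_mask inconsistent with observed vs true labels"
                    )
        elif self.flip_mask is not None:
            raise ValueError("flip_mask requires true_labels")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def has_truth(self) -> bool:
        return self.true_labels is not None

    def flipped_ids(self) -> np.ndarray:
        """Sample ids whose observed label differs from the true label."""
        if self.flip_mask is None:
            raise ValueError("dataset carries no flip mask (benchmark mode only)")
        return self.sample_ids[self.flip_mask]

    def subset(self, indices: np.ndarray) -> "LabeledDataset":
        """Row-subset view (positional indices), keeping original sample_ids."""
        idx = np.asarray(indices, dtype=int)
        return LabeledDataset(
            features=self.features[idx],
            observed_labels=self.observed_labels[idx],
            sample_ids=self.sample_ids[idx],
            true_labels=None if self.true_labels is None else self.true_labels[idx],
            flip_mask=None if self.flip_mask is None else self.flip_mask[idx],
            n_classes=self.n_classes,
        )

    def positions_of(self, ids: np.ndarray) -> np.ndarray:
        """Positional row indices of the given sample ids."""
        lookup = {int(s): i for i, s in enumerate(self.sample_ids)}
        return np.array([lookup[int(s)] for s in np.asarray(ids)], dtype=int)
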