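"""Error-identification and classification metrics.

Two set-overlap metrics quantify how well a cleansing method recovers a
known set of label errors:

* **IoU** — ``|actual ∩ predicted| / |actual ∪ predicted|``.  Penalizes both
  missed errors and clean samples wrongly flagged.
* **EIA** (error identification accuracy) — ``|actual ∩ predicted| /
  |predicted|``.  The precision of the flagged set; it never penalizes
  failing to flag an actual error, so it suits large datasets where losing
  some clean rows is harmless.

Both are unit-interval fractions internally; percentages appear only in
reporting layers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn import metrics as _skm


class UndefinedMetricError(ValueError):
    """Raised when a metric's denominator is empty (e.g. no predictions)."""


@dataclass(frozen=True)
class IdentificationCounts:
    """Raw counts behind the IoU/EIA fractions."""

    n_correct: int
    n_predicted: int
    n_actual: int

    def __post_init__(self) -> None:
        if min(self.n_correct, self.n_predicted, self.n_actual) < 0:
            raise ValueError("counts must be nonnegative")
        if self.n_correct > min(self.n_predicted, self.n_actual):
            raise ValueError("intersection cannot exceed either set")

    @property
    def n_union(self) -> int:
        return self.n_predicted + self.n_actual - self.n_correct


def identification_counts(actual_errors, predicted_errors) -> IdentificationCounts:
    actual = set(int(i) for i in actual_errors)
    predicted = set(int(i) for i in predicted_errors)
    return IdentificationCounts(
        n_correct=len(actual & predicted),
        n_predicted=len(predicted),
        n_actual=len(actual),
    )


def compute_iou(actual_errors, predicted_errors) -> float:
    """Intersection-over-union of the actual and predicted error sets."""
    c = identification_counts(actual_errors, predicted_errors)
    if c.n_union == 0:
        raise UndefinedMetricError(
            "IoU undefined: no actual errors and no predictions"
        )
    return c.n_correct / c.n_union


def compute_eia(actual_errors, predicted_errors) -> float:
    """Error identification accuracy: fraction of predictions that are real errors."""
    c = identification_counts(actual_errors, predicted_errors)
    if c.n_predicted == 0:
        raise UndefinedMetricError("EIA undefined: empty prediction set")
    return c.n_correct / c.n_predicted


@dataclass
class ClassificationReport:
    """Confusion-matrix-derived summary of a classifier's predictions.

    ``sensitivity``/``specificity`` are the recalls of the designated
    positive/negative classes.  ``per_class_accuracy`` maps each class to
    its one-vs-rest recall; classes absent from the observed labels map to
    ``nan`` (undefined, not zero).  ``roc_auc`` is binary-only.
    """

    total_accuracy: float
    sensitivity: float
    specificity: float
    per_class_accuracy: dict[int, float]
    log_loss: float
    balanced_accuracy: float
    f1: float
    roc_auc: float | None = None


def classification_report(
    predicted_labels,
    observed_labels,
    positive_class: int = 1,
    probabilities: np.ndarray | None = None,
    n_classes: int | None = None,
) -> ClassificationReport:
    """Standard classification summary against observed labels.

    ``probabilities`` (n×C), when given, feeds log loss and (binary) ROC-AUC;
    otherwise those are computed from one-hot-like hard predictions (log loss
    clipped) or left ``nan``/``None``.
    """
    y_pred = np.asarray(predicted_labels, dtype=int)
    y_true = np.asarray(observed_labels, dtype=int)
    if y_pred.shape != y_true.shape:
        raise ValueError("prediction/label length mismatch")
    C = int(n_classes or max(y_pred.max(), y_true.max()) + 1)
    labels = np.arange(C)

    total = float(np.mean(y_pred == y_true))
    per_class: dict[int, float] = {}
    for c in labels:
        present = y_true == c
        per_class[int(c)] = (
            float(np.mean(y_pred[present] == c)) if present.any() else float("nan")
        )
    negative = 1 - positive_class if C == 2 else None
    sens = per_class.get(int(positive_class), float("nan"))
    spec = per_class.get(int(negative), float("nan")) if negative is not None else float("nan")
    present_recalls = [v for v in per_class.values() if np.isfinite(v)]
    balanced = float(np.mean(present_recalls)) if present_recalls else float("nan")

    if C == 2:
        f1 = float(_skm.f1_score(y_true, y_pred, pos_label=positive_class, zero_division=0))
    else:
        f1 = float(_skm.f1_score(y_true, y_pred, average="macro", zero_division=0))

    if probabilities is not None:
        probs = np.asarray(probabilities, dtype=float)
        ll = float(_skm.log_loss(y_true, probs, labels=labels))
        auc = None
        if C == 2 and len(np.unique(y_true)) == 2:
            pos_col = probs[:, positive_class]
            y_bin = (y_true == positive_class).astype(int)
            auc = float(_skm.roc_auc_score(y_bin, pos_col))
    else:
        onehot = np.full((len(y_pred), C), 1e-12)
        onehot[np.arange(len(y_pred)), y_pred] = 1.0
        onehot /= onehot.sum(axis=1, keepdims=True)
        ll = float(_skm.log_loss(y_true, onehot, labels=labels))
        auc = None

    return ClassificationReport(
        total_accuracy=total,
        sensitivity=sens,
        specificity=spec,
        per_class_accuracy=per_class,
        log_loss=ll,
        balanced_accuracy=balanced,
        f1=f1,
        roc_auc=auc,
    )


def relative_improvement(pre_accuracy: float, post_accuracy: float) -> float:
    """Percentage improvement relative to the pre value: ``100·(post−pre)/pre``.

    Both arguments are on the same scale (both fractions or both
    percentages).  Distinct from the absolute percentage-point difference,
    which reporting layers show alongside under a separate name.
    """
    if pre_accuracy <= 0:
        raise UndefinedMetricError("relative improvement undefined for pre <= 0")
    return 100.0 * (post_accuracy - pre_accuracy) / pre_accuracy


def absolute_improvement(pre_accuracy: float, post_accuracy: float) -> float:
    """Plain difference ``post − pre`` (percentage points when inputs are %)."""
    return post_accuracy - pre_accuracy
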