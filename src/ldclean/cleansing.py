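"""Threshold selection and application for score-based data cleansing.

The cleansing threshold ``T`` is a *removal fraction*: the top
``round(T·n)`` samples of the score ranking are removed.  A heuristic
estimates ``T`` from the ensemble itself when the noise level is unknown:
the fraction of samples whose contributor-averaged probability of some
wrong class is at least ``tau``.  When the flip mask is known (benchmark
mode), every cleansing result carries IoU/EIA diagnostics against truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dataset import LabeledDataset
from .ensemble import PredictionTensor
from .ldc import NoiseScoreTable
from .metrics import compute_eia, compute_iou
from .udc import ConsensusTable

logger = logging.getLogger(__name__)


def round_half_away(x: float) -> int:
    """Round half away from zero, so e.g. 28.2% of 1000 is 282 everywhere."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


@dataclass
class CleansingThreshold:
    """Removal fraction plus how it was chosen."""

    removal_fraction: float
    source: str = "user"  # user | heuristic | sweep
    tau: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.removal_fraction < 1:
            raise ValueError("removal fraction must lie in [0, 1)")
        if self.tau is not None and not 0.5 <= self.tau < 1:
            raise ValueError("tau must lie in [0.5, 1)")


@dataclass
class CleansingResult:
    """Removal decision plus (benchmark mode) error-identification diagnostics."""

    removed_ids: np.ndarray
    retained_ids: np.ndarray
    threshold: CleansingThreshold
    iou: float | None = None
    eia: float | None = None

    @property
    def n_removed(self) -> int:
        return len(self.removed_ids)


def estimate_threshold(
    tensor: PredictionTensor, observed_labels: np.ndarray, tau: float = 0.7
) -> CleansingThreshold:
    """Heuristic removal fraction from confidently-wrong ensemble predictions.

    Averages contributor probabilities per sample; a sample counts as
    suspect when some class other than its observed label carries averaged
    probability >= tau.
    """
    if not 0.5 <= tau < 1:
        raise ValueError("tau must lie in [0.5, 1)")
    labels = np.asarray(observed_labels, dtype=int)
    mean_probs = tensor.mean_probs()
    wrong = mean_probs.copy()
    wrong[np.arange(len(labels)), labels] = -np.inf
    suspect = wrong.max(axis=1) >= tau
    return CleansingThreshold(
        removal_fraction=float(np.mean(suspect)), source="heuristic", tau=tau
    )


def apply_threshold(
    scores: NoiseScoreTable | ConsensusTable,
    threshold: CleansingThreshold | float,
    dataset: LabeledDataset | None = None,
) -> CleansingResult:
    """Remove the top ``round(T·n_scored)`` samples of the score ranking.

    Ties at the cutoff break by ascending sample id.  With a flip mask
    available the result carries IoU and EIA of the removed set against the
    actually-flipped set.  Removal emptying a class entirely logs a warning
    but proceeds.
    """
    if not isinstance(threshold, CleansingThreshold):
        threshold = CleansingThreshold(removal_fraction=float(threshold))
    ranked = scores.ranked_ids()
    n_scored = len(ranked)
    n_remove = round_half_away(threshold.removal_fraction * n_scored)
    removed = np.sort(ranked[:n_remove])
    retained = np.sort(ranked[n_remove:])

    iou = eia = None
    if dataset is not None:
        if dataset.flip_mask is not None:
            actual = dataset.flipped_ids()
            # restrict truth to the scored ids (single-model mode scores a subset)
            actual = np.intersect1d(actual, ranked)
            if n_remove > 0:
                iou = compute_iou(actual, removed)
                eia = compute_eia(actual, removed)
        scored_pos = dataset.positions_of(retained)
        retained_labels = dataset.observed_labels[scored_pos]
        for c in range(dataset.n_classes):
            if np.any(dataset.observed_labels == c) and not np.any(retained_labels == c):
                logger.warning("cleansing removed every sample of class %d", c)
    return CleansingResult(
        removed_ids=removed, retained_ids=retained, threshold=threshold,
        iou=iou, eia=eia,
    )


def cleanse_dataset(
    dataset: LabeledDataset, result: CleansingResult
) -> LabeledDataset:
    """Dataset restricted to the retained (and, in single-model mode, unscored) ids."""
    keep = np.setdiff1d(dataset.sample_ids, result.removed_ids)
    return dataset.subset(dataset.positions_of(keep))


def threshold_sweep(
    scores: NoiseScoreTable | ConsensusTable,
    dataset: LabeledDataset,
    t_grid: list[float],
) -> list[dict]:
    """IoU/EIA at each removal fraction of a grid (benchmark mode only).

    Rows are ``{"T", "n_removed", "iou", "eia"}``; at T = 0 both metrics are
    reported as absent (None), not zero, since no predictions were made.
    """
    if dataset.flip_mask is None:
        raise ValueError("threshold sweep requires a flip mask (benchmark mode)")
    rows = []
    for t in t_grid:
        result = apply_threshold(scores, CleansingThreshold(float(t), source="sweep"),
                                 dataset)
        rows.append(
            {"T": float(t), "n_removed": result.n_removed,
             "iou": result.iou, "eia": result.eia}
        )
    return rows
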