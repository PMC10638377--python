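"""Untrainable-data-cleansing (UDC) consensus baseline.

UDC scores each sample by the number of contributors whose predicted class
(argmax of the probability row) disagrees with the observed label.  With
M contributors the score is an integer in 0..M, so its histogram has at
most M+1 bins — the resolution is bounded by ensemble size, which is the
limitation the continuous LDC score removes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble import PredictionTensor


def default_bands(m_total: int) -> tuple[tuple[int, int], tuple[int, int]]:
    """Default (noisy, mislabeled) count bands, scaled from the 15-model rule.

    With 15 contributors: counts of 7–8 read as noisy, >= 9 as mislabeled;
    for other ensemble sizes the band edges scale proportionally.
    """
    noisy_low = int(np.ceil(0.45 * m_total))
    mislabel_low = min(m_total, max(int(np.ceil(0.6 * m_total)), noisy_low + 1))
    return (noisy_low, mislabel_low - 1), (mislabel_low, m_total)


@dataclass
class ConsensusTable:
    """Per-sample count of contributors disagreeing with the observed label."""

    sample_ids: np.ndarray
    counts: np.ndarray
    m_total: int
    noisy_band: tuple[int, int]
    mislabel_band: tuple[int, int]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.min() < 0 or self.counts.max() > self.m_total:
            raise ValueError("counts must lie in 0..m_total")
        if self.noisy_band[1] >= self.mislabel_band[0]:
            raise ValueError("mislabel band must sit strictly above the noisy band")

    def ranked_ids(self) -> np.ndarray:
        """Sample ids by descending disagreement count; ties by ascending id."""
        order = np.lexsort((self.sample_ids, -self.counts))
        return self.sample_ids[order]

    @property
    def mean_raw(self) -> np.ndarray:
        # alias so cleansing can rank either score table uniformly
        return self.counts


def consensus_counts(
    tensor: PredictionTensor,
    observed_labels: np.ndarray,
    sample_ids: np.ndarray | None = None,
    noisy_band: tuple[int, int] | None = None,
    mislabel_band: tuple[int, int] | None = None,
) -> ConsensusTable:
    """Count, per sample, the contributors whose argmax class is wrong.

    Argmax ties resolve to the lowest class index (numpy convention).
    """
    labels = np.asarray(observed_labels, dtype=int)
    if tensor.n_samples != len(labels):
        raise ValueError("tensor does not cover the label vector")
    predicted = tensor.probs.argmax(axis=2)  # (contributors, samples)
    counts = np.sum(predicted != labels[None, :], axis=0)
    m_total = tensor.n_contributors
    auto_noisy, auto_mislabel = default_bands(m_total)
    ids = np.arange(len(labels)) if sample_ids is None else np.asarray(sample_ids)
    return ConsensusTable(
        sample_ids=ids,
        counts=counts,
        m_total=m_total,
        noisy_band=noisy_band or auto_noisy,
        mislabel_band=mislabel_band or auto_mislabel,
    )


def consensus_histogram(
    table: ConsensusTable, group_labels: np.ndarray | None = None
) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """One integer bin per possible count 0..M, optionally split by group."""
    edges = np.arange(table.m_total + 2) - 0.5
    if group_labels is None:
        group_labels = np.zeros(len(table.counts), dtype=int)
    group_labels = np.asarray(group_labels, dtype=int)
    counts = {
        int(g): np.histogram(table.counts[group_labels == g], bins=edges)[0]
        for g in np.unique(group_labels)
    }
    return edges, counts
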