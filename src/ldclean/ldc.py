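"""Label-clustering label-noise confidence scoring (LDC).

For each contributor's full-dataset probability matrix, a K-means model
with one cluster per class is fitted to the probability rows.  Each sample
is scored ``a − b`` where ``a`` is its Euclidean distance to the centroid
mandated to its *observed* class and ``b`` the minimum distance to any
other class's centroid — positive means the sample sits closer to another
class's centroid than to its own, i.e. its label looks wrong.  Raw scores
are averaged over contributors and min–max rescaled onto [0, 100] to give
the label-noise confidence score: high ⇒ likely mislabeled, mid ⇒
noisy/ambiguous, low ⇒ likely correct.  The construction is inspired by
silhouette-style intra/inter-cluster distances but uses the difference, not
the silhouette ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from sklearn.model_selection import train_test_split

from .dataset import LabeledDataset
from .ensemble import ModelSpec, PredictionTensor, train_and_select

logger = logging.getLogger(__name__)

_KMEANS_TOL = 1e-6
_KMEANS_MAX_ITER = 300


class ScoringError(RuntimeError):
    """Raised when no contributor produced a usable clustering."""


@dataclass
class ClassCentroids:
    """K-means centroids in probability space, one per class.

    ``centroids[c]`` is the centroid mandated to class ``c`` (Hungarian
    matching of centroids to the one-hot simplex vertices).  ``degenerate``
    flags collapsed clusterings (an empty cluster, or all rows identical).
    """

    centroids: np.ndarray
    class_of_centroid: np.ndarray
    degenerate: bool = False


@dataclass
class NoiseScoreTable:
    """Per-sample raw, averaged and normalized label-noise scores.

    ``raw_scores`` is contributors × samples (NaN where a contributor did
    not score a sample); ``normalized`` spans [0, 100] with the extrema
    attained unless all mean raw scores coincide (then every score is 50
    and ``degenerate`` is set).  ``unscored_ids`` lists samples carrying no
    score at all (single-model mode's validation split).
    """

    sample_ids: np.ndarray
    raw_scores: np.ndarray
    mean_raw: np.ndarray
    normalized: np.ndarray
    contributor_count: np.ndarray
    degenerate: bool = False
    unscored_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def ranked_ids(self) -> np.ndarray:
        """Sample ids sorted by descending score; ties by ascending id."""
        order = np.lexsort((self.sample_ids, -self.mean_raw))
        return self.sample_ids[order]


def _wcss(probs: np.ndarray, centroids: np.ndarray) -> float:
    d = cdist(probs, centroids)
    return float((d.min(axis=1) ** 2).sum())


def _lloyd(probs: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, bool]:
    """Plain Lloyd iterations; returns (centroids, any_empty_cluster)."""
    C = centroids.shape[0]
    empty_cluster = False
    for _ in range(_KMEANS_MAX_ITER):
        assign = cdist(probs, centroids).argmin(axis=1)
        new_centroids = centroids.copy()
        empty_cluster = False
        for c in range(C):
            members = probs[assign == c]
            if len(members):
                new_centroids[c] = members.mean(axis=0)
            else:
                empty_cluster = True
        shift = np.linalg.norm(new_centroids - centroids, axis=1).max()
        centroids = new_centroids
        if shift < _KMEANS_TOL:
            break
    return centroids, empty_cluster


def _binary_optimal_centroids(probs: np.ndarray) -> np.ndarray:
    """Exact 2-means on binary probability rows.

    Rows ``(1-p, p)`` lie on a line segment, so the optimal 2-partition is
    a threshold split of the sorted ``p`` values; an O(n log n) prefix-sum
    scan over the n-1 splits finds the global within-cluster
    sum-of-squares minimum exactly.
    """
    p = np.sort(probs[:, 1])
    n = len(p)
    csum = np.cumsum(p)
    csq = np.cumsum(p**2)
    k = np.arange(1, n)  # left cluster sizes
    left_ss = csq[k - 1] - csum[k - 1] ** 2 / k
    rsum = csum[-1] - csum[k - 1]
    rsq = csq[-1] - csq[k - 1]
    right_ss = rsq - rsum**2 / (n - k)
    best = int(np.argmin(left_ss + right_ss))
    m0 = csum[best] / (best + 1)
    m1 = (csum[-1] - csum[best]) / (n - best - 1)
    return np.array([[1 - m0, m0], [1 - m1, m1]])


def fit_label_clusters(
    probs: np.ndarray, observed_labels: np.ndarray
) -> ClassCentroids:
    """K-means on probability rows with exactly one cluster per class.

    For two classes the rows are effectively one-dimensional and the
    globally optimal 2-means partition is computed exactly by a threshold
    scan.  For more classes, Lloyd iterations run from two deterministic
    seedless initializations — the per-observed-label mean rows
    (label-anchored) and the one-hot vertices — keeping the lower
    within-cluster sum of squares; convergence at centroid shift < 1e-6 or
    300 iterations.  Centroids are then mandated to classes by
    minimum-cost bipartite assignment against the one-hot vertices.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(observed_labels, dtype=int)
    n, C = probs.shape
    if C < 2:
        raise ValueError("need at least two classes")
    if n < C:
        raise ValueError(f"too few samples ({n}) for {C} clusters")

    vertices = np.eye(C)
    all_identical = bool(np.all(probs == probs[0]))
    if C == 2 and not all_identical:
        centroids = _binary_optimal_centroids(probs)
        empty_cluster = False
    else:
        anchored = np.empty((C, C))
        for c in range(C):
            members = probs[labels == c]
            anchored[c] = members.mean(axis=0) if len(members) else vertices[c]
        candidates = [_lloyd(probs, anchored), _lloyd(probs, vertices.copy())]
        centroids, empty_cluster = min(
            candidates, key=lambda ce: _wcss(probs, ce[0])
        )

    cost = cdist(centroids, vertices)
    row_ind, col_ind = linear_sum_assignment(cost)
    class_of_centroid = np.empty(C, dtype=int)
    class_of_centroid[row_ind] = col_ind
    by_class = np.empty_like(centroids)
    by_class[class_of_centroid] = centroids
    return ClassCentroids(
        centroids=by_class,
        class_of_centroid=class_of_centroid,
        degenerate=empty_cluster or all_identical,
    )


def raw_noise_score(
    prob_row: np.ndarray, own_centroid: np.ndarray, other_centroids: np.ndarray
) -> float:
    """``a − b``: distance to the own-class centroid minus the nearest other."""
    a = float(np.linalg.norm(prob_row - own_centroid))
    b = float(np.min(np.linalg.norm(np.atleast_2d(other_centroids) - prob_row, axis=1)))
    return a - b


def contributor_raw_scores(
    probs: np.ndarray, observed_labels: np.ndarray, centroids: ClassCentroids
) -> np.ndarray:
    """Vectorized ``a − b`` for every sample under one contributor's centroids."""
    labels = np.asarray(observed_labels, dtype=int)
    dists = cdist(np.asarray(probs, dtype=float), centroids.centroids)
    n = len(labels)
    a = dists[np.arange(n), labels]
    masked = dists.copy()
    masked[np.arange(n), labels] = np.inf
    b = masked.min(axis=1)
    return a - b


def aggregate_and_normalize(
    raw_scores: np.ndarray, sample_ids: np.ndarray | None = None
) -> NoiseScoreTable:
    """Average raw scores over contributors, then min–max rescale onto [0, 100].

    Averaging happens *before* the single global normalization, so the
    normalized column preserves the mean-raw ordering exactly.  NaN entries
    mark samples a contributor did not score.
    """
    raw = np.atleast_2d(np.asarray(raw_scores, dtype=float))
    n = raw.shape[1]
    ids = np.arange(n) if sample_ids is None else np.asarray(sample_ids, dtype=int)
    count = np.sum(~np.isnan(raw), axis=0)
    if np.any(count == 0):
        raise ValueError("every sample must be scored by at least one contributor")
    mean_raw = np.nanmean(raw, axis=0)
    lo, hi = mean_raw.min(), mean_raw.max()
    if hi - lo < 1e-300:
        return NoiseScoreTable(
            sample_ids=ids, raw_scores=raw, mean_raw=mean_raw,
            normalized=np.full(n, 50.0), contributor_count=count, degenerate=True,
        )
    normalized = 100.0 * (mean_raw - lo) / (hi - lo)
    # pin the extrema exactly despite floating-point rounding
    normalized[mean_raw == lo] = 0.0
    normalized[mean_raw == hi] = 100.0
    return NoiseScoreTable(
        sample_ids=ids, raw_scores=raw, mean_raw=mean_raw,
        normalized=normalized, contributor_count=count,
    )


def ldc_scores(tensor: PredictionTensor, dataset: LabeledDataset) -> NoiseScoreTable:
    """Full LDC scoring of a dataset from its prediction tensor.

    Each contributor's probability matrix is clustered independently;
    contributors whose clustering collapsed are dropped from the average
    with a warning.
    """
    if tensor.n_samples != dataset.n_samples:
        raise ValueError("tensor was not built over this dataset")
    rows = []
    for idx in range(tensor.n_contributors):
        centroids = fit_label_clusters(tensor.probs[idx], dataset.observed_labels)
        if centroids.degenerate:
            logger.warning(
                "contributor %s produced a degenerate clustering; excluded",
                tensor.contributors[idx],
            )
            continue
        rows.append(
            contributor_raw_scores(tensor.probs[idx], dataset.observed_labels, centroids)
        )
    if not rows:
        raise ScoringError("all contributors produced degenerate clusterings")
    return aggregate_and_normalize(np.stack(rows), dataset.sample_ids)


def single_model_ldc(
    spec: ModelSpec,
    dataset: LabeledDataset,
    val_fraction: float = 0.2,
    metric_name: str = "log_loss",
    seed: int = 0,
) -> NoiseScoreTable:
    """LDC from a single model's self-consistency.

    One model is trained with a held-out validation split used only for
    best-epoch selection; since that split steered the selection, its
    samples are excluded from scoring and reported as unscored.
    """
    if not 0 < val_fraction < 1:
        raise ValueError("val_fraction must lie in (0, 1)")
    n = dataset.n_samples
    C = dataset.n_classes
    n_train = n - int(round(val_fraction * n))
    if n_train < max(2 * C, C + 1) or n - n_train < 1:
        raise ValueError("dataset too small for the requested validation fraction")
    positions = np.arange(n)
    train_pos, val_pos = train_test_split(
        positions,
        test_size=val_fraction,
        random_state=seed,
        stratify=dataset.observed_labels,
    )
    train_pos = np.sort(train_pos)
    val_pos = np.sort(val_pos)
    model, _ = train_and_select(
        spec,
        dataset.subset(train_pos),
        dataset.subset(val_pos),
        metric_name,
        n_classes=C,
    )
    probs_all = model.predict_proba(dataset.features)
    scored_probs = probs_all[train_pos]
    scored_labels = dataset.observed_labels[train_pos]
    centroids = fit_label_clusters(scored_probs, scored_labels)
    if centroids.degenerate:
        raise ScoringError("single-model clustering collapsed")
    raw = contributor_raw_scores(scored_probs, scored_labels, centroids)
    table = aggregate_and_normalize(raw[None, :], dataset.sample_ids[train_pos])
    table.unscored_ids = dataset.sample_ids[val_pos]
    return table


def score_histogram(
    scores: np.ndarray,
    bin_count: int,
    group_labels: np.ndarray | None = None,
    value_range: tuple[float, float] = (0.0, 100.0),
) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Equal-width binned counts of scores, optionally split by group.

    Bins are right-open except the last, which is closed, so the top of the
    range lands in the final bin.  Returns (bin_edges, {group: counts}).
    """
    if bin_count < 2:
        raise ValueError("bin_count must be >= 2")
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    edges = np.linspace(value_range[0], value_range[1], bin_count + 1)
    if group_labels is None:
        group_labels = np.zeros(len(scores), dtype=int)
    group_labels = np.asarray(group_labels, dtype=int)
    counts = {
        int(g): np.histogram(scores[group_labels == g], bins=edges)[0]
        for g in np.unique(group_labels)
    }
    return edges, counts
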