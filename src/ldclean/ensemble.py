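"""Cross-validated ensemble training and full-dataset prediction.

The label-noise scorers consume a *prediction tensor*: for each contributor
— one (model configuration, cross-validation fold) pair — an n×C matrix of
class probabilities over the **entire** dataset, including the rows the
contributor trained on.  Each contributor trains on the dataset minus its
fold, selects its best epoch by a validation metric evaluated on that fold
(log loss by default), restores the best-epoch parameters, and then runs
inference everywhere.  Contrasting configurations and rotating validation
folds are what make the ensemble's disagreements informative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as _skm
from sklearn.model_selection import KFold, StratifiedKFold

from .dataset import LabeledDataset
from .nn import Network, build_network

logger = logging.getLogger(__name__)

EPOCH_METRICS = ("log_loss", "total_accuracy", "balanced_accuracy", "f1", "roc_auc")


@dataclass
class ModelSpec:
    """One model configuration (architecture + hyperparameters)."""

    architecture: str = "mlp"
    hidden_sizes: list[int] = field(default_factory=lambda: [150, 30])
    branch_activations: list[str] = field(
        default_factory=lambda: ["sigmoid", "tanh", "relu"]
    )
    conv_channels: int = 4
    kernel_size: int = 5
    dropout_rate: float = 0.1
    learning_rate: float = 0.05
    epochs: int = 30
    batch_size: int = 32
    optimizer_name: str = "sgd"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ("mlp", "multi_branch_mlp", "conv1d"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class FoldPlan:
    """Assignment of every sample to one of k cross-validation folds."""

    k: int
    fold_of_sample: np.ndarray
    stratified: bool
    seed: int

    def val_positions(self, i: int) -> np.ndarray:
        return np.where(self.fold_of_sample == i)[0]

    def train_positions(self, i: int) -> np.ndarray:
        return np.where(self.fold_of_sample != i)[0]


@dataclass
class EpochTrace:
    """Per-epoch validation-metric values and the selected best epoch."""

    metric_name: str
    values: list[float]
    best_epoch: int


@dataclass
class PredictionTensor:
    """Per-contributor full-dataset class-probability matrices.

    ``probs`` has shape (n_contributors, n_samples, n_classes); every row of
    every contributor matrix lies on the probability simplex.
    """

    contributors: list[tuple[int, int]]
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 3:
            raise ValueError("probs must be (contributors, samples, classes)")
        if len(self.contributors) != self.probs.shape[0]:
            raise ValueError("contributor list does not match probs")
        if self.probs.min() < -1e-9:
            raise ValueError("negative probabilities")
        sums = self.probs.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1")

    @property
    def n_contributors(self) -> int:
        return self.probs.shape[0]

    @property
    def n_samples(self) -> int:
        return self.probs.shape[1]

    @property
    def n_classes(self) -> int:
        return self.probs.shape[2]

    def mean_probs(self) -> np.ndarray:
        """Contributor-averaged n×C probability matrix."""
        return self.probs.mean(axis=0)


class TrainedModel:
    """Opaque trained-model handle: standardization stats + network."""

    def __init__(self, network: Network, mean: np.ndarray, std: np.ndarray):
        self._net = network
        self._mean = mean
        self._std = std

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        x = np.asarray(features, dtype=float)
        if x.shape[1] != self._mean.shape[0]:
            raise ValueError(
                f"feature dimension {x.shape[1]} does not match model "
                f"({self._mean.shape[0]})"
            )
        return self._net.predict_proba((x - self._mean) / self._std)


def kfold_partition(
    dataset: LabeledDataset, k: int, stratified: bool = True, seed: int = 0
) -> FoldPlan:
    """Partition the dataset into k disjoint folds (stratified by observed label)."""
    if k < 2:
        raise ValueError("k must be >= 2 (use single_model_ldc for one model)")
    if stratified:
        _, counts = np.unique(dataset.observed_labels, return_counts=True)
        if k > counts.min():
            raise ValueError("k exceeds the smallest class count under stratification")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(dataset.features, dataset.observed_labels)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(dataset.features)
    fold_of_sample = np.empty(dataset.n_samples, dtype=int)
    for i, (_, val_idx) in enumerate(splits):
        fold_of_sample[val_idx] = i
    return FoldPlan(k=k, fold_of_sample=fold_of_sample, stratified=stratified, seed=seed)


def _evaluate_metric(
    metric_name: str, y_val: np.ndarray, probs: np.ndarray, n_classes: int
) -> float:
    labels = np.arange(n_classes)
    preds = probs.argmax(axis=1)
    if metric_name == "log_loss":
        return float(_skm.log_loss(y_val, probs, labels=labels))
    if metric_name == "total_accuracy":
        return float(np.mean(preds == y_val))
    if metric_name == "balanced_accuracy":
        return float(_skm.balanced_accuracy_score(y_val, preds))
    if metric_name == "f1":
        avg = "binary" if n_classes == 2 else "macro"
        return float(_skm.f1_score(y_val, preds, average=avg, zero_division=0))
    if metric_name == "roc_auc":
        if n_classes != 2:
            raise ValueError("roc_auc epoch selection is binary-only")
        return float(_skm.roc_auc_score(y_val, probs[:, 1]))
    raise ValueError(f"unknown epoch-selection metric {metric_name!r}")


def metric_is_loss(metric_name: str) -> bool:
    return metric_name == "log_loss"


def train_and_select(
    spec: ModelSpec,
    train_split: LabeledDataset,
    val_split: LabeledDataset,
    metric_name: str = "log_loss",
    n_classes: int | None = None,
    restore_best: bool = True,
) -> tuple[TrainedModel, EpochTrace]:
    """Train one model; keep the parameters of its best validation epoch.

    Best epoch = argmin for log loss, argmax for the other metrics; the
    earliest epoch wins ties.  Features are column-standardized with
    statistics from the training split only.  With ``restore_best=False``
    the final-epoch parameters are kept (training-to-convergence mode);
    the trace still records the per-epoch metric and best epoch.
    """
    if metric_name not in EPOCH_METRICS:
        raise ValueError(f"metric_name must be one of {EPOCH_METRICS}")
    C = int(n_classes or max(train_split.n_classes, val_split.n_classes))
    if metric_name == "roc_auc" and C != 2:
        raise ValueError("roc_auc epoch selection is binary-only")

    mean = train_split.features.mean(axis=0)
    std = train_split.features.std(axis=0)
    std = np.where(std < 1e-12, 1.0, std)
    x_train = (train_split.features - mean) / std
    x_val = (val_split.features - mean) / std
    y_train = train_split.observed_labels
    y_val = val_split.observed_labels

    net = build_network(
        spec.architecture,
        input_dim=train_split.n_features,
        n_classes=C,
        hidden_sizes=list(spec.hidden_sizes),
        branch_activations=list(spec.branch_activations),
        conv_channels=spec.conv_channels,
        kernel_size=spec.kernel_size,
        dropout_rate=spec.dropout_rate,
        seed=spec.seed,
    )

    values: list[float] = []
    best = {"epoch": -1, "value": None, "params": None}
    lower_better = metric_is_loss(metric_name)

    def after_epoch(epoch: int) -> None:
        probs = net.predict_proba(x_val)
        value = _evaluate_metric(metric_name, y_val, probs, C)
        values.append(value)
        better = (
            best["value"] is None
            or (lower_better and value < best["value"])
            or (not lower_better and value > best["value"])
        )
        if better:
            best["epoch"] = epoch
            best["value"] = value
            best["params"] = net.get_params()

    try:
        net.fit(
            x_train,
            y_train,
            epochs=spec.epochs,
            learning_rate=spec.learning_rate,
            batch_size=spec.batch_size,
            optimizer=spec.optimizer_name,
            seed=spec.seed + 1,
            callback=after_epoch,
        )
    except FloatingPointError as exc:
        raise FloatingPointError(f"{exc} [spec={spec}]") from exc

    if restore_best:
        net.set_params(best["params"])
    trace = EpochTrace(metric_name=metric_name, values=values, best_epoch=best["epoch"])
    return TrainedModel(net, mean, std), trace


def predict_full(model: TrainedModel, dataset: LabeledDataset) -> np.ndarray:
    """Class probabilities for every sample in the dataset (evaluation mode)."""
    return model.predict_proba(dataset.features)


def derive_contributor_seed(global_seed: int, m: int, i: int) -> int:
    """Deterministic per-contributor seed so contributors differ in init."""
    return int(np.random.SeedSequence([global_seed, m, i]).generate_state(1)[0] % (2**31))


def build_prediction_tensor(
    dataset: LabeledDataset,
    specs: list[ModelSpec],
    fold_plan: FoldPlan,
    metric_name: str = "log_loss",
    trace_log: list | None = None,
) -> PredictionTensor:
    """Train every (spec, fold) contributor and predict over the whole dataset.

    Contributor ordering is spec-major, fold-minor and stable.  Each
    contributor's own seed derives from (spec.seed, m, i).
    """
    if not specs:
        raise ValueError("need at least one model spec")
    contributors: list[tuple[int, int]] = []
    all_probs = []
    for m, spec in enumerate(specs):
        for i in range(fold_plan.k):
            sub_seed = derive_contributor_seed(spec.seed, m, i)
            sub_spec = ModelSpec(**{**spec.__dict__, "seed": sub_seed})
            train_ds = dataset.subset(fold_plan.train_positions(i))
            val_ds = dataset.subset(fold_plan.val_positions(i))
            try:
                model, trace = train_and_select(
                    sub_spec, train_ds, val_ds, metric_name, n_classes=dataset.n_classes
                )
            except Exception as exc:
                raise RuntimeError(f"contributor (m={m}, i={i}) failed: {exc}") from exc
            best_value = trace.values[trace.best_epoch]
            logger.info(
                "contributor m=%d i=%d best_epoch=%d %s=%.5f",
                m, i, trace.best_epoch, metric_name, best_value,
            )
            if trace_log is not None:
                trace_log.append(
                    {"m": m, "i": i, "metric_name": metric_name,
                     "best_epoch": trace.best_epoch, "value": best_value}
                )
            contributors.append((m, i))
            all_probs.append(predict_full(model, dataset))
    return PredictionTensor(contributors=contributors, probs=np.stack(all_probs))
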