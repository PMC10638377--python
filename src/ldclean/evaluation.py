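"""End-to-end orchestration: score → cleanse → retrain → compare.

The pre/post comparison trains the same model configuration on the
uncleansed and the cleansed training set and reports both on the *cleansed*
validation split (and optionally on an uncleansed held-back test split,
the real-world check).  Comparison models train to convergence and are
evaluated at their final epoch, so that the damage noisy labels do to a
converged model — and the uplift from removing them — is what gets
measured; their per-epoch validation-loss traces also yield a training
stability figure (standard deviation of validation loss over the last 10
epochs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.decomposition import PCA
from sklearn.model_selection import train_test_split

from . import cleansing as _cleansing
from .dataset import LabeledDataset
from .ensemble import (
    ModelSpec,
    PredictionTensor,
    build_prediction_tensor,
    derive_contributor_seed,
    kfold_partition,
    train_and_select,
)
from .ldc import NoiseScoreTable, ldc_scores, single_model_ldc
from .metrics import (
    ClassificationReport,
    absolute_improvement,
    classification_report,
    relative_improvement,
)
from .synthetic import SyntheticSpec, generate_hard, generate_separable
from .udc import ConsensusTable, consensus_counts

logger = logging.getLogger(__name__)

MODES = ("ldc", "udc", "single_model_ldc")


@dataclass
class RunConfig:
    """Resolved configuration of one cleansing run."""

    dataset_path: str | None = None
    label_column: str = "label"
    synthetic: dict | None = None  # SyntheticSpec fields + "generator"
    model_specs: list[ModelSpec] = field(default_factory=lambda: [ModelSpec()])
    k: int = 5
    metric_name: str = "log_loss"
    mode: str = "ldc"
    threshold: float | None = None
    estimate_threshold: bool = False
    tau: float = 0.7
    val_fraction: float = 0.2
    holdout_fraction: float = 0.0
    repeats: int = 3
    comparison_spec: ModelSpec | None = None
    min_train_samples: int = 50
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.mode == "single_model_ldc" and len(self.model_specs) != 1:
            raise ValueError("single-model mode requires exactly one model spec")
        if self.dataset_path is None and self.synthetic is None:
            raise ValueError("config needs a dataset path or a synthetic spec")


@dataclass
class RunArtifacts:
    """Everything one scoring/cleansing run produced."""

    dataset: LabeledDataset
    tensor: PredictionTensor | None
    scores: NoiseScoreTable | ConsensusTable
    threshold: _cleansing.CleansingThreshold | None = None
    cleansing: _cleansing.CleansingResult | None = None
    trace_log: list[dict] = field(default_factory=list)


@dataclass
class ComparisonReport:
    """Pre- vs post-cleansing model performance, averaged over repeats."""

    repeats: int
    pre_reports: list[ClassificationReport]
    post_reports: list[ClassificationReport]
    pre_accuracy: float
    post_accuracy: float
    pre_per_class: dict[int, float]
    post_per_class: dict[int, float]
    relative_improvement_pct: float
    absolute_improvement_points: float
    pre_stability: float
    post_stability: float
    test_pre_accuracy: float | None = None
    test_post_accuracy: float | None = None
    n_train_pre: int = 0
    n_train_post: int = 0


def load_or_generate_dataset(config: RunConfig) -> LabeledDataset:
    if config.dataset_path is not None:
        from .io import read_dataset

        return read_dataset(config.dataset_path, label_column=config.label_column)
    params = dict(config.synthetic)
    generator = params.pop("generator", "separable")
    params.setdefault("seed", config.seed)
    spec = SyntheticSpec(**params)
    if generator == "separable":
        return generate_separable(spec)
    if generator == "hard":
        return generate_hard(spec)
    raise ValueError(f"unknown synthetic generator {generator!r}")


def score_dataset(
    config: RunConfig, dataset: LabeledDataset
) -> tuple[PredictionTensor | None, NoiseScoreTable | ConsensusTable, list[dict]]:
    """Train contributors and score the dataset under the configured mode."""
    trace_log: list[dict] = []
    if config.mode == "single_model_ldc":
        table = single_model_ldc(
            config.model_specs[0], dataset, config.val_fraction,
            config.metric_name, seed=config.seed,
        )
        return None, table, trace_log
    plan = kfold_partition(dataset, config.k, stratified=True, seed=config.seed)
    tensor = build_prediction_tensor(
        dataset, config.model_specs, plan, config.metric_name, trace_log=trace_log
    )
    if config.mode == "ldc":
        return tensor, ldc_scores(tensor, dataset), trace_log
    return tensor, consensus_counts(
        tensor, dataset.observed_labels, dataset.sample_ids
    ), trace_log


def run_scoring(config: RunConfig, dataset: LabeledDataset | None = None) -> RunArtifacts:
    """Score and (when a threshold is configured) cleanse a dataset."""
    ds = dataset if dataset is not None else load_or_generate_dataset(config)
    tensor, scores, trace_log = score_dataset(config, ds)
    art = RunArtifacts(dataset=ds, tensor=tensor, scores=scores, trace_log=trace_log)
    if config.estimate_threshold:
        if tensor is None:
            raise ValueError("threshold estimation needs an ensemble tensor")
        art.threshold = _cleansing.estimate_threshold(
            tensor, ds.observed_labels, config.tau
        )
    elif config.threshold is not None:
        art.threshold = _cleansing.CleansingThreshold(config.threshold, source="user")
    if art.threshold is not None:
        art.cleansing = _cleansing.apply_threshold(scores, art.threshold, ds)
    return art


def _stratified_ids(
    dataset: LabeledDataset, fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """(rest_ids, held_ids) from a stratified split on observed labels."""
    pos = np.arange(dataset.n_samples)
    rest, held = train_test_split(
        pos, test_size=fraction, random_state=seed,
        stratify=dataset.observed_labels,
    )
    return dataset.sample_ids[np.sort(rest)], dataset.sample_ids[np.sort(held)]


def _train_eval(
    spec: ModelSpec,
    train_ds: LabeledDataset,
    val_ds: LabeledDataset,
    n_classes: int,
    extra_eval: LabeledDataset | None = None,
) -> tuple[ClassificationReport, float, ClassificationReport | None]:
    """Train to convergence, report final-epoch model on the validation split.

    Returns (report, stability, extra_report); stability is the standard
    deviation of the per-epoch validation log loss over the last 10 epochs.
    """
    model, trace = train_and_select(
        spec, train_ds, val_ds, "log_loss", n_classes=n_classes, restore_best=False
    )
    tail = trace.values[-10:]
    stability = float(np.std(tail))
    probs = model.predict_proba(val_ds.features)
    report = classification_report(
        probs.argmax(axis=1), val_ds.observed_labels,
        probabilities=probs, n_classes=n_classes,
    )
    extra_report = None
    if extra_eval is not None:
        ep = model.predict_proba(extra_eval.features)
        extra_report = classification_report(
            ep.argmax(axis=1), extra_eval.observed_labels,
            probabilities=ep, n_classes=n_classes,
        )
    return report, stability, extra_report


def run_pre_post_comparison(
    config: RunConfig, dataset: LabeledDataset | None = None
) -> tuple[ComparisonReport, RunArtifacts]:
    """Full pipeline: cleanse, then compare models trained pre vs post.

    A held-back test split (uncleansed) is withdrawn first when configured;
    it never enters the cleansing process.  The cleansed validation split is
    withdrawn from the *cleansed* data; pre-models train on everything else
    uncleansed, post-models on everything else cleansed.
    """
    full = dataset if dataset is not None else load_or_generate_dataset(config)
    holdout: LabeledDataset | None = None
    work = full
    if config.holdout_fraction > 0:
        rest_ids, held_ids = _stratified_ids(
            full, config.holdout_fraction, config.seed + 101
        )
        holdout = full.subset(full.positions_of(held_ids))
        work = full.subset(full.positions_of(rest_ids))

    art = run_scoring(config, work)
    if art.cleansing is None:
        raise ValueError("pre/post comparison needs a threshold (set or estimated)")
    cleansed = _cleansing.cleanse_dataset(work, art.cleansing)

    train_ids_clean, val_ids = _stratified_ids(
        cleansed, config.val_fraction, config.seed + 202
    )
    val_ds = cleansed.subset(cleansed.positions_of(val_ids))
    post_train = cleansed.subset(cleansed.positions_of(train_ids_clean))
    pre_ids = np.setdiff1d(work.sample_ids, val_ids)
    pre_train = work.subset(work.positions_of(pre_ids))

    if post_train.n_samples < config.min_train_samples:
        raise ValueError(
            f"cleansed training set has {post_train.n_samples} samples "
            f"(< {config.min_train_samples}); lower the threshold T"
        )

    base = config.comparison_spec or ModelSpec(
        hidden_sizes=[150, 30], epochs=60, learning_rate=0.05, dropout_rate=0.1
    )
    C = work.n_classes
    pre_reports, post_reports = [], []
    pre_stab, post_stab = [], []
    test_pre, test_post = [], []
    for rep in range(config.repeats):
        rep_seed = derive_contributor_seed(config.seed + 303, rep, 0)
        spec = ModelSpec(**{**base.__dict__, "seed": rep_seed})
        r_pre, s_pre, t_pre = _train_eval(spec, pre_train, val_ds, C, holdout)
        r_post, s_post, t_post = _train_eval(spec, post_train, val_ds, C, holdout)
        pre_reports.append(r_pre)
        post_reports.append(r_post)
        pre_stab.append(s_pre)
        post_stab.append(s_post)
        if holdout is not None:
            test_pre.append(t_pre.total_accuracy)
            test_post.append(t_post.total_accuracy)

    pre_acc = float(np.mean([r.total_accuracy for r in pre_reports]))
    post_acc = float(np.mean([r.total_accuracy for r in post_reports]))

    def _mean_per_class(reports: list[ClassificationReport]) -> dict[int, float]:
        out = {}
        for c in range(C):
            vals = [r.per_class_accuracy.get(c, float("nan")) for r in reports]
            out[c] = float(np.nanmean(vals)) if np.any(np.isfinite(vals)) else float("nan")
        return out

    report = ComparisonReport(
        repeats=config.repeats,
        pre_reports=pre_reports,
        post_reports=post_reports,
        pre_accuracy=pre_acc,
        post_accuracy=post_acc,
        pre_per_class=_mean_per_class(pre_reports),
        post_per_class=_mean_per_class(post_reports),
        relative_improvement_pct=relative_improvement(pre_acc, post_acc),
        absolute_improvement_points=absolute_improvement(
            100 * pre_acc, 100 * post_acc
        ),
        pre_stability=float(np.mean(pre_stab)),
        post_stability=float(np.mean(post_stab)),
        test_pre_accuracy=float(np.mean(test_pre)) if test_pre else None,
        test_post_accuracy=float(np.mean(test_post)) if test_post else None,
        n_train_pre=pre_train.n_samples,
        n_train_post=post_train.n_samples,
    )
    return report, art


def pca_model_score_map(
    tensor: PredictionTensor,
    labels: np.ndarray,
    use_raw_noise_scores: bool = False,
    raw_scores: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """2-d PCA map of per-sample model scores.

    By default the input columns are every contributor's probability row
    concatenated (n × M·C, standardized); alternatively per-contributor raw
    noise scores can be projected.  Returns (n×2 coordinates, explained
    variance ratios); component 1 explains at least as much variance as
    component 2.
    """
    if use_raw_noise_scores:
        if raw_scores is None:
            raise ValueError("raw_scores required when use_raw_noise_scores=True")
        X = np.asarray(raw_scores, dtype=float).T  # contributors × n -> n × M
    else:
        X = np.transpose(tensor.probs, (1, 0, 2)).reshape(tensor.n_samples, -1)
    if X.shape[1] < 2:
        raise ValueError("need at least two score columns for a 2-d map")
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    X = X / np.where(sd < 1e-12, 1.0, sd)
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(X)
    evr = pca.explained_variance_ratio_
    if evr[1] < 1e-12:
        logger.warning("model-score matrix is effectively rank one")
    return coords, evr


def resolved_config(config: RunConfig) -> dict[str, Any]:
    """JSON-serializable dictionary of every (defaulted) config value."""
    out = dict(config.__dict__)
    out["model_specs"] = [dict(s.__dict__) for s in config.model_specs]
    if config.comparison_spec is not None:
        out["comparison_spec"] = dict(config.comparison_spec.__dict__)
    return out
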