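"""Delimited-text readers and writers for every run artifact.

All tabular artifacts are comma-delimited text with headers; configuration
is JSON or YAML (by extension).  Every writer has a matching reader so
artifacts round-trip.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cleansing import CleansingResult, CleansingThreshold
from .dataset import LabeledDataset
from .ensemble import ModelSpec
from .evaluation import ComparisonReport, RunConfig, resolved_config
from .ldc import NoiseScoreTable
from .udc import ConsensusTable

logger = logging.getLogger(__name__)


# -- datasets ---------------------------------------------------------------

def read_dataset(path: str | Path, label_column: str = "label") -> LabeledDataset:
    """Load a delimited-text dataset: numeric feature columns + integer labels.

    Optional ``true_label`` and ``flipped`` columns (benchmark mode) are
    recognized.  Non-contiguous label values are compacted to 0..C-1 with a
    logged mapping.
    """
    df = pd.read_csv(path)
    if label_column not in df.columns:
        raise ValueError(f"missing label column {label_column!r} in {path}")
    special = {label_column, "true_label", "flipped", "sample_id"}
    feature_cols = [c for c in df.columns if c not in special]
    features = df[feature_cols]
    bad = features.columns[~features.apply(
        lambda col: pd.api.types.is_numeric_dtype(col))]
    if len(bad):
        raise ValueError(f"non-numeric feature column(s): {list(bad)}")
    observed = df[label_column].to_numpy()
    true = df["true_label"].to_numpy() if "true_label" in df.columns else None

    values = np.unique(observed if true is None else np.concatenate([observed, true]))
    mapping = {int(v): i for i, v in enumerate(values)}
    if any(k != v for k, v in mapping.items()):
        logger.info("compacted label values with mapping %s", mapping)
    observed = np.array([mapping[int(v)] for v in observed])
    if true is not None:
        true = np.array([mapping[int(v)] for v in true])

    sample_ids = (
        df["sample_id"].to_numpy() if "sample_id" in df.columns else None
    )
    ds = LabeledDataset(
        features=features.to_numpy(dtype=float),
        observed_labels=observed,
        sample_ids=sample_ids,
        true_labels=true,
        n_classes=len(values),
    )
    counts = np.bincount(ds.observed_labels, minlength=ds.n_classes)
    logger.info("read %d rows, %d features, class counts %s",
                ds.n_samples, ds.n_features, counts.tolist())
    return ds


def write_dataset(dataset: LabeledDataset, path: str | Path) -> None:
    cols = {f"f{j}": dataset.features[:, j] for j in range(dataset.n_features)}
    df = pd.DataFrame(cols)
    df.insert(0, "sample_id", dataset.sample_ids)
    df["label"] = dataset.observed_labels
    if dataset.true_labels is not None:
        df["true_label"] = dataset.true_labels
        df["flipped"] = dataset.flip_mask.astype(int)
    df.to_csv(path, index=False)


# -- scores and histograms --------------------------------------------------

def write_scores(
    table: NoiseScoreTable | ConsensusTable,
    path: str | Path,
    dataset: LabeledDataset | None = None,
) -> None:
    if isinstance(table, NoiseScoreTable):
        df = pd.DataFrame(
            {
                "sample_id": table.sample_ids,
                "mean_raw": table.mean_raw,
                "normalized": table.normalized,
                "contributor_count": table.contributor_count,
            }
        )
    else:
        df = pd.DataFrame(
            {"sample_id": table.sample_ids, "disagreement_count": table.counts}
        )
    if dataset is not None:
        pos = dataset.positions_of(df["sample_id"].to_numpy())
        df["observed_label"] = dataset.observed_labels[pos]
        if dataset.true_labels is not None:
            df["true_label"] = dataset.true_labels[pos]
            df["flipped"] = dataset.flip_mask[pos].astype(int)
    df.to_csv(path, index=False)


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_histogram(
    edges: np.ndarray, counts: dict[int, np.ndarray], path: str | Path
) -> None:
    rows = []
    for group, c in counts.items():
        for b in range(len(c)):
            rows.append(
                {"group": group, "bin_low": edges[b], "bin_high": edges[b + 1],
                 "count": int(c[b])}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# -- cleansing --------------------------------------------------------------

def write_cleansing(result: CleansingResult, path: str | Path) -> None:
    ids = np.concatenate([result.removed_ids, result.retained_ids])
    removed = np.concatenate(
        [np.ones(len(result.removed_ids), int), np.zeros(len(result.retained_ids), int)]
    )
    order = np.argsort(ids)
    pd.DataFrame({"sample_id": ids[order], "removed": removed[order]}).to_csv(
        path, index=False
    )


def write_sweep(rows: list[dict], path: str | Path) -> None:
    pd.DataFrame(rows).to_csv(path, index=False)


# -- reports and configuration ----------------------------------------------

def write_comparison(report: ComparisonReport, path: str | Path) -> None:
    def _rep(r):
        d = dataclasses.asdict(r)
        d["per_class_accuracy"] = {str(k): v for k, v in d["per_class_accuracy"].items()}
        return d

    payload = dataclasses.asdict(report)
    payload["pre_reports"] = [_rep(r) for r in report.pre_reports]
    payload["post_reports"] = [_rep(r) for r in report.post_reports]
    payload["pre_per_class"] = {str(k): v for k, v in report.pre_per_class.items()}
    payload["post_per_class"] = {str(k): v for k, v in report.post_per_class.items()}
    Path(path).write_text(json.dumps(payload, indent=2, default=float))


def write_config(config: RunConfig, path: str | Path) -> None:
    payload = resolved_config(config)
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=2, default=float))


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    payload = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    specs = [ModelSpec(**s) for s in payload.pop("model_specs", [{}])]
    comp = payload.pop("comparison_spec", None)
    comparison = ModelSpec(**comp) if comp else None
    return RunConfig(model_specs=specs, comparison_spec=comparison, **payload)


def write_trace_log(trace_log: list[dict], path: str | Path) -> None:
    pd.DataFrame(trace_log).to_csv(path, index=False)


def write_outputs(
    artifacts: dict[str, object], directory: str | Path, overwrite: bool = False
) -> dict[str, Path]:
    """Write every known artifact into a directory; refuse collisions.

    Recognized keys: dataset, scores (with dataset context), histogram
    (edges, counts), cleansing, sweep, comparison, config, trace_log.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    writers = {
        "dataset": ("dataset.csv", lambda v, p: write_dataset(v, p)),
        "scores": ("scores.csv",
                   lambda v, p: write_scores(v, p, artifacts.get("dataset"))),
        "histogram": ("histogram.csv", lambda v, p: write_histogram(v[0], v[1], p)),
        "cleansing": ("cleansing.csv", lambda v, p: write_cleansing(v, p)),
        "sweep": ("sweep.csv", lambda v, p: write_sweep(v, p)),
        "comparison": ("comparison.json", lambda v, p: write_comparison(v, p)),
        "config": ("resolved_config.json", lambda v, p: write_config(v, p)),
        "trace_log": ("training_log.csv", lambda v, p: write_trace_log(v, p)),
    }
    written: dict[str, Path] = {}
    for key, value in artifacts.items():
        if key not in writers or value is None:
            continue
        name, writer = writers[key]
        target = directory / name
        if target.exists() and not overwrite:
            raise FileExistsError(f"{target} exists (pass overwrite=True)")
        writer(value, target)
        written[key] = target
    return written
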