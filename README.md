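# ldclean — label-clustering data cleansing

`ldclean` detects mislabeled and noisy records in tabular classification
datasets *before* a final model is trained, with no prior annotation of
which samples are wrong.  It is aimed at datasets — medical records are
the motivating case — where labels come from subjective or error-prone
processes and manual review is impractical, and at anyone who needs to
quantify how much a dataset's labels can be trusted.

## The method

Train M contrasting model configurations across k cross-validation folds
(each contributor trains on 𝔻∖𝔻⁽ⁱ⁾, selects its best epoch by validation
log loss on 𝔻⁽ⁱ⁾, then predicts class probabilities for **all** of 𝔻).
For each contributor, fit K-means to its n×C probability matrix with one
centroid mandated per class, and score every sample

    l̄ⱼ = a − b

where *a* is the Euclidean distance from the sample's probability row to
the centroid of its *observed* class and *b* the distance to the nearest
other class's centroid.  A sample whose predictions sit near another
class's centroid (a > b) looks mislabeled.  Scores are averaged over the
M·k contributors and min–max rescaled to **0–100**: high ⇒ likely
mislabeled, mid ⇒ noisy/ambiguous, low ⇒ likely correct.  The top
fraction T of the ranking is then removed before final training.

The package also implements:

* **UDC**, the consensus baseline — the number of contributors whose
  predicted class disagrees with the observed label (integer 0..M·k);
* **error-identification metrics** for benchmarks with known flips:
  IoU = |actual ∩ predicted| / |actual ∪ predicted| and
  EIA = |actual ∩ predicted| / |predicted|;
* **threshold tools**: sweeps of IoU/EIA vs T, and a heuristic T from
  confidently-wrong averaged ensemble predictions;
* **synthetic benchmarks**: a clean separable Gaussian-cluster dataset
  with exact, tracked label flips, and a hard overlapping-cluster dataset
  with ~74% Bayes-optimal accuracy;
* a **pre/post evaluation harness** (retrain on uncleansed vs cleansed
  data, report on a cleansed validation split), single-model scoring,
  score histograms and 2-d PCA maps of model scores.

Record models (plain MLP, multi-branch MLP with contrasting activations,
1-D CNN) run on a small built-in numpy engine with minibatch SGD,
per-epoch validation traces and best-epoch snapshots.

## Worked example

```python
import ldclean as L

# clean two-class dataset (500/class, 20 features) with 30% tracked flips
ds = L.generate_separable(L.SyntheticSpec(
    n_per_class=[500, 500], n_features=20, class_separation=6.0,
    flip_rate=0.3, seed=42))

# 1 MLP spec x 5 folds = 5 contributors; score and cleanse at T = 0.30
spec = L.ModelSpec(hidden_sizes=[150, 30], epochs=40, learning_rate=0.01)
plan = L.kfold_partition(ds, k=5, seed=0)
tensor = L.build_prediction_tensor(ds, [spec], plan)
table = L.ldc_scores(tensor, ds)
result = L.apply_threshold(table, 0.30, ds)
print(result.eia, result.iou)
```

Running `python examples/02_ldc_scoring.py` (this pipeline plus a
histogram) prints:

```
contributors: 5
score range: [0, 100]
mean score, clean samples:     12.1
mean score, flipped samples:   73.2

removed 300 samples at T=0.30
EIA = 0.943  (fraction of removed samples actually flipped)
IoU = 0.893  (overlap of removed set with the flipped set)
```

94% of the removed samples really were flipped, and the removed set
covers the flipped set almost exactly.  `examples/05_pre_post_uplift.py`
closes the loop — retraining after cleansing lifts validation accuracy
from 68.3% to 97.1% (+42.2% relative) and shrinks the training-loss
oscillation by ~8×.  The other examples cover data generation, the UDC
comparison, threshold sweeps, single-model scoring and PCA maps.

A `ldclean` command-line tool wraps the same pipeline
(`simulate` / `score` / `cleanse` / `sweep` / `evaluate` / `plot` /
`pca-map`); see `ldclean --help`.

## Documentation

`docs/methods.md` describes the model, its assumptions, every tunable
parameter, the synthetic-data design, numerical choices and known
limitations.
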