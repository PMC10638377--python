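# Methods

## Problem setting

A tabular classification dataset carries *observed* labels that may
disagree with the (unknown) true classes.  Two failure modes matter:
**mislabeling** — the features clearly support one class but the label
says another — and **noise/ambiguity** — the features do not support a
confident call either way.  The toolkit assigns every sample a position
on that spectrum a priori, from the self-consistency of models trained on
the data itself, with no sample-level annotation of which labels are
wrong.

## Label-clustering scoring (LDC)

**Contributors.**  M model configurations × k cross-validation folds.
Contributor (m, i) trains on 𝔻∖𝔻⁽ⁱ⁾, selects its best epoch by a
validation metric on 𝔻⁽ⁱ⁾ (log loss by default; total/balanced accuracy,
F1 and binary ROC-AUC are selectable), restores the best-epoch
parameters, and predicts class probabilities for the whole of 𝔻 in
evaluation mode.  Rotating folds and contrasting configurations give the
contributors different biases; their pooled geometry, not any single
model's opinion, drives the score.  A held-back test split, when used,
is withdrawn before 𝔻 is defined and never touches the cleansing.

**Clustering.**  Per contributor, K-means with K = C clusters is fitted
to the n×C probability rows and each centroid is mandated to one class by
minimum-cost bipartite assignment against the one-hot simplex vertices.
The sample score is a − b (distance to own-class centroid minus distance
to the nearest other-class centroid); for C = 2 the "nearest other" is
the only other.  The construction is silhouette-inspired but uses the
difference, not the silhouette ratio, so it is unbounded and linear in
distance.

**Aggregation.**  Raw a − b scores are averaged over contributors first,
then a single global min–max rescaling maps the means onto [0, 100]
(averaging before normalization preserves the mean-raw ordering exactly;
normalizing per contributor first would weight contributors by their
score spread).  If every mean coincides the table is flagged degenerate
and all scores are 50.  Contributors whose clustering collapsed (an
empty cluster, or identical rows) are dropped from the average with a
warning; scoring fails only if none survive.

**Single-model mode.**  One model, no fold rotation: a stratified
validation split (default 20%) steers best-epoch selection and is
therefore excluded from scoring — those samples carry an explicit
unscored marker.  Clustering is fitted on the scored subset only.

## UDC consensus baseline

Per sample, the number of contributors whose argmax class disagrees with
the observed label (ties to the lowest class index).  The count is an
integer in 0..M·k, so histogram resolution is capped at M·k+1 bins;
the continuous LDC score removes that cap without training more models.
Default interpretation bands scale from the 15-contributor reading
(counts 7–8 noisy, ≥9 mislabeled) as ⌈0.45M⌉ and ⌈0.6M⌉; they are user
thresholds, fully configurable.

## Cleansing threshold

T is a **removal fraction**: the top `round_half_away(T·n_scored)`
samples of the score ranking are removed, ties at the cutoff broken by
ascending sample id.  Removal sets are nested in T.  When the noise
level is unknown, a heuristic estimates T as the fraction of samples
whose contributor-averaged probability of some wrong class reaches τ
(default 0.7, range [0.5, 1)): τ = 0.5 counts every sample the averaged
ensemble misclassifies (upper estimate), larger τ only confidently wrong
ones.  With best-epoch ensembles that stop at a soft optimum the default
is deliberately conservative.  Benchmark runs attach IoU and EIA of the
removed set against the flip mask; a removal that empties a class logs a
warning rather than failing, since aggressive thresholds (up to 40%) are
legitimate.

## Error-identification metrics

IoU = |actual ∩ predicted| / |actual ∪ predicted| penalizes both missed
errors and wrongly flagged clean samples; EIA = |actual ∩ predicted| /
|predicted| is the precision of the flagged set and ignores misses.
Both are unit-interval fractions internally; percentages appear only in
reports.  EIA with an empty prediction set raises rather than returning
0, so threshold sweeps report the T = 0 row as absent — a silent zero
would corrupt peak-finding.  Improvement between two accuracies is
reported both as relative (100·(post−pre)/pre, the headline convention)
and as absolute percentage points, labeled distinctly.

## Synthetic benchmarks

`generate_separable` draws per-class Gaussian clusters with unit
within-class spread; class means sit on scaled basis vectors so every
pair is exactly `class_separation` apart.  The clean preset (d = 20,
separation 6, 1000/class) is classifiable at >99% by a nearest-centroid
rule — errors introduced by flips are the *only* errors.
`inject_label_flips` switches exactly `round(ρ·n_c)` labels per class
(uniformly chosen samples, uniformly chosen different target class), so
metric targets are deterministic given the seed; ρ < 0.5 keeps flips a
minority.  `generate_hard` lowers the separation to 1.2866, where the
two-Gaussian Bayes accuracy Φ(sep/2) ≈ 0.74 — inherent ambiguity with no
flip mask.

What the generator does **not** emulate: real records' feature
correlations, class imbalance beyond what is configured, heteroscedastic
noise, and structured (feature-dependent) mislabeling — synthetic flips
are independent of the features.  Passing tests therefore demonstrate
error *recovery under separable geometry with uniform flips*; on real
data the score distribution is typically less bimodal and thresholds
need the histogram/heuristic tools.

## Record models and training

Three architectures cover the record-model family: a plain MLP (default
hidden sizes 150/30), a multi-branch MLP whose parallel input branches
use sigmoid/tanh/relu activations before concatenation, and a 1-D CNN
(valid-mode convolution over the feature axis, then dense layers).  All
run on a compact numpy engine: He-scaled initialization, inverted
dropout after the first hidden layer (default rate 0.1), softmax
cross-entropy, minibatch SGD with momentum 0.9 (Adam selectable),
default learning rate 0.05, batch 32.  Training is deterministic given
the seed; per-contributor seeds derive from (spec seed, m, i) so
contributors differ in initialization.  Features are column-standardized
with statistics from each contributor's training split only, avoiding
validation leakage.  Backpropagation is verified against numerical
differentiation in the test suite.

Study-scale defaults (2×1000 samples, 20 features, 40 epochs, 5 folds)
were chosen so a full 5-contributor scoring run completes in seconds on
one CPU; the defaults are configuration, not limits.

## Pre/post evaluation harness

After cleansing, a stratified validation split (default 20%) is
withdrawn from the *cleansed* data.  r models (default 3) train on the
uncleansed remainder and r on the cleansed remainder; both are reported
on the cleansed validation split, and optionally on the uncleansed
held-back test split.  Comparison models train to convergence and are
evaluated at their **final** epoch: the harness measures what label
noise does to a converged model, which is the regime where noisy labels
get fitted — best-epoch early stopping would partially mask the damage
the cleansing is supposed to prevent.  The per-epoch validation-loss
trace yields the training-stability figure (standard deviation over the
last 10 epochs).  The report stores every per-repeat metric.

## Numerical choices

* **Binary clustering is solved exactly.**  For C = 2 the probability
  rows lie on a line segment, so the optimal 2-means partition is a
  threshold split of the sorted rows, found exactly by an O(n log n)
  prefix-sum scan.  (Lloyd iterations from a single deterministic
  initialization can stall in local optima on adversarial instances;
  the exact scan removes that failure mode entirely.)
* For C > 2, Lloyd runs from two deterministic seedless
  initializations — the per-observed-label mean rows and the one-hot
  vertices — keeping the lower within-cluster sum of squares;
  convergence at centroid shift < 1e-6 or 300 iterations.
* Multi-class *b* is the minimum distance over other classes' centroids
  (alternatives such as mean distance are deliberately not offered).
* Removal counts round half away from zero, so 28.2% of 1000 is 282
  everywhere; ranking ties break by ascending sample id.
* Min–max normalization pins the extrema to exactly 0 and 100 despite
  floating-point rounding.
* Epoch-metric ties select the earliest epoch.
* PCA maps standardize the concatenated contributor probability columns
  before projection; a per-contributor raw-score variant is available by
  flag.

## Known limitations

* Scores are relative within a dataset (min–max over the run); they are
  not calibrated probabilities and do not transfer across datasets.
* A single model's scores are noticeably noisier than an ensemble's:
  on the clean flipped benchmark, single-model EIA runs several points
  below the 5-contributor ensemble, whose EIA is near saturation there.
* When all contributors share one bias (e.g. all underfit a class), the
  consensus inherits it; contrasting architectures mitigate but cannot
  eliminate this.
* The flip-injection model is feature-independent; systematic,
  feature-correlated mislabeling will look more like the "hard" regime
  and resist exact recovery.
* ROC-AUC epoch selection is binary-only; there is no multi-class AUC
  extension.
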