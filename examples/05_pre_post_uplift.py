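"""Measure the accuracy uplift from cleansing before retraining.

Runs the full pipeline — score, remove the top 30%, withdraw a cleansed
validation split — then trains the same model configuration three times on
the uncleansed and the cleansed training data, reporting both on the
cleansed validation split.  Converged models trained on 30%-flipped data
fit the noise; removing it restores near-perfect accuracy and much
smoother training.
"""

import ldclean as L

cfg = L.RunConfig(
    synthetic={"n_per_class": [500, 500], "n_features": 20,
               "class_separation": 6.0, "flip_rate": 0.3,
               "generator": "separable"},
    model_specs=[L.ModelSpec(hidden_sizes=[150, 30], epochs=40,
                             learning_rate=0.01)],
    k=5,
    threshold=0.30,
    repeats=3,
    seed=21,
)
report, art = L.run_pre_post_comparison(cfg)

print(f"removed {art.cleansing.n_removed} samples "
      f"(EIA {art.cleansing.eia:.3f}, IoU {art.cleansing.iou:.3f})")
print(f"pre-cleansing accuracy:  {100 * report.pre_accuracy:5.1f}%")
print(f"post-cleansing accuracy: {100 * report.post_accuracy:5.1f}%")
print(f"relative improvement:    {report.relative_improvement_pct:+5.1f}%")
print(f"absolute improvement:    {report.absolute_improvement_points:+5.1f} points")
print("per-class accuracy post:",
      {c: round(v, 3) for c, v in report.post_per_class.items()})
print(f"training stability (std of val loss, last 10 epochs): "
      f"pre {report.pre_stability:.4f} vs post {report.post_stability:.4f}")
print("\nThe pre-model fits the flipped labels and generalizes them; after")
print("cleansing the same configuration trains stably to ~99% accuracy.")
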