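"""Nearest-centroid subtype classification with Spearman correlation.

Centroids are per-gene class means; a sample joins the best-correlated
class unless all correlations fall below 0.1 (then it is unclassified).
Accuracy is estimated by leave-one-out cross-validation.
"""

import angiosig as ag

cfg = ag.SimulationConfig(n_tumor=200, n_normal=0, n_background_genes=0, seed=3)
expr, ann, truth = ag.generate_cohort(cfg)
panel = ag.subset_panel(expr, cfg.panel)

model = ag.fit_centroids(panel, truth.cluster, correlation_threshold=0.1)
assigned = ag.classify(model, panel)
print(f"classes: {model.class_names}")
print(f"unclassified samples: {(assigned['label'] == ag.UNCLASSIFIED).sum()}")

acc, confusion = ag.loocv(panel, truth.cluster)
print(f"LOOCV accuracy: {acc:.3f}")
print(confusion)
# Accuracy well above chance (1/7) shows the planted clusters carry
# rank-detectable centroid signatures; confusions concentrate between the
# clusters with the most similar shift patterns.
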