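# angiosig

Angiogenesis-related gene expression defines subgroups of breast cancer —
in particular of triple-negative breast cancer (TNBC) — with different
pro/anti-angiogenic balance and different prognosis. `angiosig` is a tested,
reusable implementation of the full analysis workflow for studying this on
log2 expression matrices: expression-based receptor-status calling,
nearest-centroid subtype classification, Wilcoxon differential expression,
PCA signature discovery with clinical association, consensus K-means subtype
discovery, and survival analysis. A first-class synthetic-cohort generator
reproduces the statistical structure these analyses assume, so the entire
workflow runs and is verified end-to-end without any external data.

It is aimed at computational biologists analysing bulk breast-tumor
expression cohorts (microarray or gene-level RNA-Seq) who need these stages
as a library rather than a collection of one-off scripts.

## Methods at a glance

- **Receptor status.** For receptor genes ESR1/PGR/ERBB2, class-conditional
  trivariate Gaussians are fit to IHC-labeled TN and receptor-positive (RP)
  samples; unlabeled samples are called by the posterior
  P(TN | x) = π φ_TN(x) / (π φ_TN(x) + (1−π) φ_RP(x)), with any IHC-positive
  receptor overriding the model.
- **Subtype classification.** Nearest-centroid (PAM50-style): class
  centroids are per-gene means; a sample joins the class with the highest
  Spearman correlation ρ, or is *unclassified* if all ρ < 0.1. Accuracy by
  leave-one-out cross-validation.
- **Differential expression.** Wilcoxon rank-sum test (exact for n+m ≤ 20
  without ties), effect size log2(mean(2^x)/mean(2^y)), and a 99%
  Hodges–Lehmann confidence interval obtained by inverting the rank-sum
  test on a log2-scale location shift.
- **PCA signatures.** Centered (optionally scaled) PCA over the 31-gene
  VEGF/semaphorin panel; deterministic loading signs; logistic regression
  of clinical variables on the first 8 scores; Wilks' Λ = det(W)/det(T)
  MANOVA with the Bartlett χ² approximation for 2-D score separation.
- **Consensus clustering.** Best-of-50-restart Lloyd K-means; 100 rounds on
  80% subsamples build a consensus matrix of co-clustering fractions; K is
  chosen where the area under the consensus-CDF stops increasing
  appreciably.
- **Survival.** Kaplan–Meier product-limit curves, log-rank tests, and Cox
  proportional hazards (Newton–Raphson partial likelihood, Efron or Breslow
  ties) with univariate/multivariate hazard-ratio tables over clinical
  factors and median-dichotomized signature scores.

The 31-gene panel spans the VEGF ligands and receptors (VEGFA/B/C, PGF,
FLT1, KDR, FLT4), both neuropilins, semaphorin classes 3–7 and the plexins.

## Worked example

```python
import angiosig as ag

cfg = ag.SimulationConfig(n_tumor=400, n_normal=30, seed=42)
expr, ann, truth = ag.generate_cohort(cfg)
print(expr.shape, truth.tn.mean())
```

```
(534, 430) 0.2175
```

534 genes (31 panel + 3 receptor + 500 background) by 430 samples, with
21.8% of tumors truly triple-negative. Calling receptor status from
expression (see `examples/02_receptor_status.py`):

```
prior P(TN) among labeled samples: 0.176
misclassification vs simulated truth: 2.000%
```

The Gaussian-density caller mislabels 2% of tumors against the simulated
truth — the same order as the expression-vs-IHC mismatch reported for real
cohorts. Consensus clustering on a planted 3-cluster cohort
(`examples/06_consensus_clustering.py`):

```
K=2: CDF area 0.454, relative change 0.454
K=3: CDF area 0.672, relative change 0.482
K=4: CDF area 0.726, relative change 0.079
chosen K: 3 (planted: 3)
adjusted Rand index vs planted clusters: 1.000
```

The consensus-CDF area jumps by ~48% going to the planted K and by <8%
beyond it, and the final K-means labels match the planted clusters exactly.
Each script in `examples/` demonstrates one capability and prints what the
numbers mean; `examples/08_full_pipeline.py` runs all seven stages under
one seed via `ag.run_pipeline`, and the same pipeline is exposed as a thin
CLI (`angiosig pipeline --seed 11 --out demo_out`).

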