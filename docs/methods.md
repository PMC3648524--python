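# Methods

This note documents the models implemented in `angiosig`, the parameter
choices that matter, what the synthetic-cohort generator does and does not
emulate, and the numerical conventions. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The gene panel

The default panel (`angiosig/panels/vegf_sema.txt`, loaded as
`VEGF_SEMA_PANEL`) holds 31 VEGF- and semaphorin-related genes: the VEGF
ligands VEGFA, VEGFB, VEGFC and PGF; the receptors FLT1 (VEGFR1), KDR
(VEGFR2) and FLT4 (VEGFR3); the co-receptors NRP1 and NRP2; the secreted
class-3 semaphorins SEMA3A/3B/3C/3E/3F/3G; the membrane-associated
semaphorins SEMA4A/4D/4F/4G, SEMA5A/5B, SEMA6A/6B and SEMA7A; and the
plexins PLXNA1, PLXNA3, PLXNB1/B2/B3, PLXNC1 and PLXND1. These two families
compete for neuropilin co-receptors on endothelial cells, which is why
their joint expression pattern — not any single gene — is the object of
analysis. SEMA3D and VEGFD are deliberately not in the default panel; any
user panel can be supplied as a `GenePanel`.

Expression is assumed to arrive already log2-normalized (e.g. RMA
microarray output or log RNA-Seq gene-level values); no renormalization is
performed anywhere. Probe-level matrices are collapsed to gene level by
keeping, per gene, the probe with the highest sample variance (n−1
denominator, all samples jointly); exact ties keep the first probe in input
order, and the chosen probe is recorded.

## Synthetic cohort generator

`generate_cohort(SimulationConfig)` draws, per tumor:

- a planted cluster c with configured mixing proportions; the tumor's panel
  expression is `baseline_mean + shift_c + N(0, noise_sd²)` iid per gene
  (log2 scale);
- receptor-gene expression for ESR1/PGR/ERBB2 from independent
  two-component Gaussian mixtures (negative vs positive component); the
  triple-negative truth is "all three receptors drawn from the negative
  component";
- IHC labels equal to the true component, flipped with probability
  `ihc_error_rate` and masked to "unknown" with probability
  `ihc_missing_rate` (independently per receptor);
- clinical covariates: stage I/II/III (0.30/0.45/0.25), nodal involvement
  (0.4), grade 1/2/3 (0.20/0.45/0.35), age ~ N(58, 12²) clipped to
  [25, 90];
- a survival time from an exponential proportional-hazards model,
  rate = `baseline_rate · exp(β_sig·s + β_TN·TN + β_stage·1[stage III] +
  β_node·node)`, where s is the tumor's centered projection onto the
  leading planted contrast direction; censoring is independent uniform
  administrative censoring on [0, τ] with τ calibrated by bisection so the
  expected censoring fraction matches the target (monotone because
  E[min(T,τ)]/τ decreases in τ).

Normals receive the unshifted panel baseline, mid-level receptor
expression, and no survival data. Background genes are iid Gaussians with
gene-level means drawn once from U(4, 12), giving probe collapsing and gene
ordering realistically sized inputs.

Defaults (chosen once as the package's study conditions): 800 tumors, 40
normals, 500 background genes; 7 planted clusters whose shift patterns
qualitatively mimic the recurring tumor groups seen in breast cohorts —
two high-VEGFA / low-SEMA3B/3C/3F clusters (one also high FLT1/FLT4/SEMA3A,
one high VEGFC/KDR/NRP1), a high-FLT1/FLT4/SEMA3A cluster with low
VEGFA/VEGFC, a high-VEGFC/KDR/NRP1/SEMA5A cluster, a mild class-4/plexin-B
cluster, and two high-class-3-semaphorin / low-VEGFA clusters; shift
magnitudes 1–2 log2 units with `noise_sd = 0.6`, giving the crisp cluster
structure consensus matrices are expected to show. Receptor mixtures are
separated by ≥4σ (clearly bimodal marginals) with positive-component
probabilities 0.50/0.45/0.15 for ER/PR/HER2, yielding ≈23% truly
triple-negative tumors. Survival uses baseline rate 0.012/month,
β_sig = −0.7, β_TN = 0.5, β_stage = 0.4, β_node = 0.6 and a 60% censoring
target — a hazard structure in which both the signature and TN status carry
real, separable prognostic signal.

What the generator does **not** emulate, and what that means for the tests:
receptor status is drawn independently of the panel clusters, so — unlike
in real breast cohorts, where the pro-angiogenic signature is strongly
enriched in TNBC — associations between PCA scores and TN status are null
by construction; those pipeline stages therefore act as type-I-error checks
on synthetic data rather than power demonstrations. Similarly, cluster
shifts largely cancel in the tumor-wide mean, so tumor-vs-normal
differential expression is mild compared to a real cohort (the
rank-sum/CI machinery is instead verified against enumeration and
test-inversion oracles). Probe-level noise models, batch effects between
pooled series, and RNA-Seq count noise are out of scope. Passing tests
demonstrate correctness of the statistical machinery under the stated
generative model, not biological fidelity of any particular dataset.

## Receptor-status calling

One Gaussian is fit per class (IHC TN vs IHC receptor-positive) on the
three receptor genes, by maximum likelihood; the TN prior is the labeled TN
fraction. Both a full trivariate covariance (default — receptor
co-expression is informative) and a diagonal per-gene variant are
available, since either reading of "a Gaussian over the three receptors" is
defensible. Covariances are regularized by adding εI with
ε = 1e-6 × mean diagonal when near-singular (floor 1e-6, so fully
degenerate classes remain usable). Posteriors are evaluated in log space;
a posterior of exactly 0.5 is called receptor-positive — the conservative
tie-break toward the class with more treatment options. Each class requires
at least 4 labeled samples. For samples with partial IHC,
`assign_tn_with_ihc` applies the rule that any IHC-positive receptor forces
an RP call (a TN call requires all three receptors negative), falling back
to the model only when IHC is uninformative.

## Centroid classification

Centroids are arithmetic per-gene class means (median available); classes
are sorted so output order is deterministic. Classification uses Spearman
correlation with average ranks for ties; the winner must reach the
correlation threshold (default 0.1) or the sample is left unclassified.
Exact correlation ties are broken by class order and logged. Model genes
absent from a query matrix are dropped pairwise, with a minimum overlap of
3 genes. LOOCV refits the centroids for every fold by default (the
statistically correct variant); a full-data-centroid mode exists for
comparison and is, as expected, optimistic. Unclassified predictions count
as errors.

## Differential expression

`rank_sum_test` delegates to the Mann–Whitney machinery: exact enumeration
when n+m ≤ 20 with no ties, otherwise the normal approximation with tie and
continuity corrections; the method used is recorded. The effect size is
log2(mean(2^x)/mean(2^y)) — means on the linear scale, then log2 — because
inputs are log2 expression and fold changes are conventionally reported on
the linear-mean scale; a difference-of-log-means mode is provided since
either convention appears in practice. The confidence interval (99%
default) inverts the rank-sum test on a location shift of the log2 values:
the p-value as a function of the shift δ is a step function changing only
at the pairwise differences x_i − y_j, so the accepted region is read off
the exact null distribution of U (computed by the standard counting
recurrence) or its normal approximation, and the interval endpoints are
order statistics of the pairwise differences. The point summary
accompanying the interval is the Hodges–Lehmann median of pairwise
differences. Intervals that cannot exclude anything at the requested level
(tiny samples) get infinite endpoints with a warning. Significance is
annotated at p < 0.001 by default (a 0.01 level is configurable); no
multiplicity correction is applied by default, with an optional
Benjamini–Hochberg column.

## PCA signatures

PCA treats samples as observations and panel genes as variables. Genes are
centered; unit-variance scaling is off by default (the heatmap z-scaling
used for visualization is a separate concern) and available as a flag.
Loadings come from the SVD of the centered matrix with a deterministic sign
convention — each loading column's largest-magnitude entry is positive — so
signatures are reproducible and comparable across datasets; explained
variances use the n−1 convention. `compare_loadings` reports the Pearson
correlation of two loading vectors on shared genes plus a sign-flip flag,
since eigenvector sign is arbitrary across fits. Logistic association fits
the outcome on the first 8 component scores jointly (per-component marginal
mode available); separation and nonconvergence are reported explicitly in a
flag column. MANOVA of 2-D scores across groups uses Wilks'
Λ = det(W)/det(T) with the Bartlett approximation
χ² = −(n−1−(p+g)/2)·lnΛ on p(g−1) degrees of freedom.

## Consensus clustering and K selection

The base clusterer is Lloyd K-means restarted from random initial centers,
keeping the restart with the smallest within-cluster sum of squares
(scikit-learn backend; empty clusters are re-seeded from the
highest-inertia points, scikit-learn's relocation rule). Full-data
clustering uses 50 restarts; the 100 consensus iterations on 80%
subsamples use 10 restarts each by default, a per-iteration cost/stability
trade-off (the subsampling itself supplies the randomization the consensus
estimate needs). Consensus values are co-clustering counts divided by
co-sampling counts (unbiased under subsampling; division by total
iterations available as an option); pairs never co-sampled are set to 0 and
counted. The per-iteration subsample/assignment log is retained so the
matrix can be audited by recount.

K is selected from the area under the empirical CDF of upper-triangle
consensus values (100-bin grid): the chosen K is the smallest whose
relative area increase to K+1 falls below `min_relative_change`. The
default threshold is 0.15. This constant deserves a note: with planted
Gaussian clusters, moving past the true K still adds ~5–10% relative area
— splitting a roughly spherical cluster moves a w² fraction of sample pairs
to diffuse consensus values — while resolving a real cluster adds ≥30%, so
0.15 sits between the two regimes. There is no universal constant for this
rule; the areas and changes are always returned so the consensus matrices
themselves can be inspected (the time-honored "most off-diagonal white
space" judgment), and on cohorts with many unevenly separated clusters the
automated rule tends to under-select K — the pipeline therefore also
reports agreement at the planted K when truth is available.

Heatmap gene ordering z-scales rows (zero-variance rows are flagged and
left unscaled), computes Euclidean distances and complete-linkage
agglomeration, and returns the dendrogram leaf order.

## Survival analysis

Kaplan–Meier estimation and the log-rank test (O−E with hypergeometric
variance across event times, df = groups−1) are delegated to lifelines.
The Cox proportional-hazards model is implemented in-package: Newton–
Raphson with step-halving on the partial likelihood, Efron tie handling by
default with Breslow switchable, standard errors from the observed
information, Wald p-values. Covariates are centered internally (coefficients
are unchanged by centering); constant covariates are rejected, and
nonconvergence raises rather than returning silently. lifelines'
`CoxPHFitter` serves as an independent cross-check in the test suite, never
as the implementation. Times and events are taken as given; an optional
administrative truncation horizon can censor events past a cutoff.
`survival_table` reproduces the usual univariate (one-covariate Cox +
log-rank for binary factors) vs multivariate (joint Cox) hazard-ratio
layout, with signature scores entered as above/below-median indicators.

## Pipeline and reproducibility

`run_pipeline` sequences simulate → receptor status → subtype →
differential expression → PCA/association → consensus clustering →
survival, validating the entire configuration before any stage runs. A
single global seed fans out to per-stage seeds via
`SeedSequence((seed, stage_index))`, so any stage can be rerun in isolation
and identical configs give byte-identical outputs. All tables are TSV, all
metadata JSON; the manifest records outputs, per-stage seeds, a SHA-256
parameter hash and summary statistics, and is persisted even when a stage
fails. The subtype stage estimates LOOCV accuracy on a stratified subsample
(default ≤150 samples) — LOOCV is quadratic in cohort size and the accuracy
estimate does not need the full cohort.

## Numerical conventions and edge cases

- Posteriors and partial likelihoods are computed in log space; logistic
  and Cox fits flag separation/nonconvergence instead of returning numbers
  silently.
- Probe-collapse ties, classification-correlation ties and k-selection
  fallbacks are deterministic and logged/warned.
- Degenerate inputs: identical-sample Gaussian classes are regularized to
  εI; all-equal score vectors dichotomize to all zeros with a warning;
  zero-variance genes are an error under PCA scaling and a warned pass-through
  under heatmap z-scaling.
- Exact rank-sum enumeration is limited to n+m ≤ 20, matching the regime
  where enumeration is both feasible and distinguishable from the
  approximation.

## Known limitations

- The synthetic cohort is the only bundled data; all quantitative claims in
  the README are about the generator's model.
- The consensus K rule cannot reproduce a visual consensus-matrix judgment;
  treat `chosen_k` as a diagnostic starting point.
- The Cox implementation covers fixed covariates only (no time-varying
  covariates, stratification or competing risks), and no proportionality
  diagnostics are provided.
- Patient-level deduplication across pooled series is the caller's
  responsibility; the readers only enforce unique sample ids.
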