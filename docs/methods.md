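# Methods note

This note records the model behind the `tepmced` package, its assumptions,
the main parameters with their defaults, the numerical choices that matter
for reproduction, and the known limitations.

## 1. Synthetic cohort model

`tepmced.cohort` simulates a platelet-RNA screening cohort on a log-like
expression scale. For sample *i* and gene *j*:

x_ij = μ_j + √ρ · F_{i,b(j)} + √(1−ρ) · ε_ij + d · s_j · y_i · 1[j ∈ I] + δ · f_i · 1[j ∈ P]

- μ_j ~ N(5, 1.5²): per-gene baseline abundance (fixed across samples).
- F: standard-normal latent factor per correlated gene block b(j) of size
  `block_size` (default 10); ρ = `block_rho` (default 0.3) is the pairwise
  within-block correlation. Genes have unit residual variance, so planted
  shifts are in standardized (Cohen's d) units.
- I: `n_informative` genes (default 20) drawn uniformly; each gets a
  class-conditional shift of magnitude `effect_size` (default d = 1.5) with a
  random sign s_j.
- P: a random 10% of genes perturbed by δ (default 0.5·d) in the flagged
  (symptomatic) controls f_i — molecular activity that makes flagged controls
  resemble cases and motivates their exclusion.

Metadata: label, cancer type (`n_types` = 18 for cases, "control"
otherwise), stage (probabilities 0.10/0.25/0.30/0.25/0.10 for I–IV/unknown),
age ~ N(58, 12²) clipped to [18, 95], sex (p = 0.5), institution (4 levels),
flagged indicator. Default composition: 1628 cancer + 390 control + 333
flagged = 2351 samples, 2000 genes.

An external cohort (`generate_external_cohort`, defaults 285 samples with 30
copied verbatim from the base cohort and a configurable gene subset) reuses
the same gene-level parameters, so the class-conditional structure of shared
genes is preserved across cohorts.

What the generator does **not** emulate: sequencing-depth/library-size
effects, count noise (data are Gaussian on the log-like scale), batch-by-gene
interactions, stage- or type-specific signatures (the planted effect is
common to all cancers), or covariate-expression dependence (age/sex do not
influence expression).

## 2. Curation and feature selection

`exclude_flagged` removes flagged samples and missing labels before any
statistic is computed. Selection then runs on a stratified discovery subset
(33% of curated samples; sklearn's stratified splitter, so the subset size is
the floor of 0.33·n):

1. per-gene one-way ANOVA across the label groups, Benjamini–Hochberg
   adjusted; q < 0.001, capped at the 300 smallest-q genes (ties to larger
   F). Constant genes get q = 1.
2. greedy Pearson pruning at |r| > 0.8, scanning genes in ascending-q order,
   so the statistically stronger member of each correlated pair survives.
   Zero-variance genes have undefined correlation, treated as r = 0 and
   logged.
3. z-scoring is *not* done here: scaler statistics are fitted inside each
   model pipeline on (resampled) fold-training rows only.

## 3. Covariate-balanced split

The balance objective ("divergence") of a test-membership vector is the sum
over the categorical covariates (label, sex, cancer type, institution) of
squared train-vs-test category-proportion gaps, plus the squared standardized
gap of mean age. The 80/20 partition (test size = round-half-even of 0.2·n,
overridable via `test_n`) is found by:

1. aggregating samples into strata = joint levels of the categorical
   covariates and solving a continuous relaxation with SLSQP over one
   test-count variable per stratum (bounds [0, stratum size], counts summing
   to the test size). This aggregation is exact for every categorical term
   and uses within-stratum mean ages for the age term; it reduces ~2000
   samples to a few hundred variables, which SLSQP solves in about a second
   (a per-sample relaxation would need minutes per solve).
2. largest-remainder rounding of the stratum counts, then 8 seeded random
   within-stratum draws keeping the best exact discrete divergence.
3. comparison against 1000 label-stratified random baselines; the final
   split is whichever of (rounded optimum, best baseline) has lower
   divergence, so the result is never worse than random search.

On the default curated cohort the optimized divergence is ≈5·10⁻⁴ against a
baseline median of ≈8·10⁻³.

## 4. Classifiers

Seven families share the fixed pipeline **resample → scale → classify**:
SMOTE (k = 5 neighbor interpolation, minority upsampled to parity; fewer
than 2 minority samples falls back to resampling with replacement), per-gene
z-scoring fitted on the resampled training data, then the classifier. The
pipeline is refitted inside each CV fold, so oversampled points and scaler
statistics never derive from validation rows (asserted by instrumented
tests).

- NN/DNN: an in-package numpy MLP (1 or 2 ReLU hidden layers with inverted
  dropout, sigmoid output, Adam with β₁ = 0.9, β₂ = 0.999, ε = 1e-7, binary
  cross-entropy, early stopping with patience 5 and best-weight restore,
  Glorot-uniform init). Search space: units {64, 128}, dropout {0.1, 0.3},
  learning rate {0.001, 0.0005}, epochs {20, 30}, batch {32, 64}.
- XGB, RF, LR, DT: the standard library implementations with conventional
  search spaces (see `tepmced.models.SEARCH_SPACES`).
- SVM: RBF `SVC` wrapped in Platt-scaling calibration for probabilities.

Tuning: randomized search (default iterations NN 8, DNN 5, XGB 10, SVM 8,
RF 10, LR 5, DT 8; seed 42) under stratified 5-fold CV scored by mean ROC
AUC, refit on the full training set. The decision threshold maximizes
Youden's J (sensitivity + specificity − 1) over midpoints of sorted unique
scores, by default on pooled out-of-fold training scores; ties resolve to
the smallest qualifying threshold.

## 5. Shapley attribution

All backends attribute the cancer-class output against an interventional
background (coalition value = expected output with coalition features set to
the sample's values and the rest drawn from background rows):

- **LR**: closed form in margin space, φ_j = β_j (x_j − mean background).
- **DT/RF** (probability) and **XGB** (margin): exact interventional
  tree-path Shapley. For each (sample, background row) pair the algorithm
  enumerates root-to-leaf paths, classifies split conditions as
  sample-satisfied or background-satisfied, and accumulates the closed-form
  coalition weights (a−1)!·b!/(a+b)! and −a!·(b−1)!/(a+b)!; numba-compiled.
  XGBoost thresholds are float32 in the engine, so parsed thresholds are
  snapped to float32 and inputs are rounded through float32 before descent —
  without this, rows sitting exactly on a threshold take the wrong branch.
  Verified against brute-force subset enumeration to ≈3·10⁻⁷.
- **SVM** (probability): kernel estimation as a weighted least-squares
  problem with the efficiency constraint imposed by substitution; coalitions
  are fully enumerated when 2^p − 2 fits the budget (then the estimate is
  exact), otherwise all singleton/complement coalitions plus
  kernel-proportional sampling. Background = 50 k-means representatives of
  the training set; evaluated samples capped at 50 (both configurable).
- **NN/DNN**: integrated gradients averaged over background references
  (32 steps); additive only up to discretization error (~10⁻⁴ here), flagged
  `additive_exact = False`.

Outlier filtering is adaptive per gene: the IQR multiplier k is scanned
descending 3.0 → 0.5 in steps of 0.25, and the first k whose out-of-bounds
fraction lies in [0.05, 0.10] wins (those values are zeroed). If no k lands
in the band, values outside the empirical 1st/99th percentiles are zeroed.
Filtered values drive global importance and the consensus; unfiltered values
drive local explanations.

## 6. Consensus and agreement

Per model, the per-gene mean-|filtered attribution| vector is min-max scaled
to [0, 1] across genes; consensus score(g) = Σ_m AUC_m · scaled_m(g) over
non-excluded models (DT excluded by default; AUC weights are used raw since
rankings are invariant to a common positive factor). Agreement is pairwise
Spearman ρ restricted to genes with nonzero importance in both models (< 3
shared genes → undefined). Cross-cohort reproducibility = top-15 overlap
between the primary consensus and the consensus recomputed on the harmonized
external cohort. Training genes absent from the external cohort are imputed
at the training mean (scaled value 0), keeping the models' input space
intact; this is reported alongside the harmonization summary.

## 7. Problem sizes and seeds

The analysis drivers and the acceptance script run a reduced-scale modeling
cohort chosen by this package (260 cancer / 140 control / 60 flagged, 600
genes, 20 informative at d = 1.5; external cohort 180 samples with 20
overlapping and 90% of genes) so the full pipeline completes in minutes on
one CPU. Full-scale checks (curation counts, split diagnostics) use the
generator defaults. All stages are deterministic under fixed seeds; the
model seed defaults to 42 and data seeds are taken from the command line.

## 8. Limitations

- Synthetic data only: Gaussian on a log-like scale, a single pan-cancer
  signature, no depth/batch artifacts — results quantify pipeline behavior,
  not clinical performance.
- The kernel backend is exact only in enumeration mode; in sampling mode
  accuracy depends on the coalition budget (additivity always holds via the
  efficiency constraint).
- Integrated gradients is a path method, not exact Shapley; it is used for
  the nets where exact enumeration is impractical.
- The stratum-aggregated split relaxation treats age through stratum means;
  within-stratum age imbalance is only controlled via the seeded draws.
- The auto-interaction heuristic in dependence exports (median-split slope
  difference) is a declared heuristic, not an estimator of any formal
  interaction index.
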