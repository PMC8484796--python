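# Methods

This note documents the models and estimators implemented in `m6ascape`,
the defaults they ship with, what the synthetic-cohort generator does and
does not emulate, and the numerical choices made where the design was open.

## Synthetic cohorts

`simulate_cohort` generates the study conditions every downstream stage
assumes.  Defaults (all overridable on `SimulationConfig`):

| parameter | default | meaning |
|---|---|---|
| `n_samples`, `n_cohorts` | 150, 2 | 300 samples across two cohorts, comparable to a TCGA+ICGC pancreatic study |
| `cluster_proportion` π | 0.5 | P(sample belongs to cluster B); labels are Bernoulli draws |
| `cluster_effect` Δ | 2.0 | mean shift, in within-cluster SD units, added to all 21 regulator genes in cluster B |
| `batch_shift`/`batch_scale` | (0, 1) / (1, 1.3) | per-cohort affine transform x·scale + shift applied to every gene |
| `baseline_hazard` λ | 1/1000 per day | exponential baseline; median OS ln2/λ ≈ 693 days, a realistic pancreatic-cancer scale |
| `beta_cluster` | ln 2 | planted log hazard ratio of cluster B vs A |
| `censor_rate` | 0.4 | between typical TCGA (~48% alive) and ICGC (~23% alive) fractions |
| `signature_sets` | 2 × 20 genes, shift ±1 | pathway genes activated/repressed in cluster B |
| `mutation_freqs` | ZC3H13 11%, RBM15B 9%, YTHDF1 8%, YTHDC1 6%, KRAS 90%, TP53 50/60% | per-gene, per-cluster Bernoulli probabilities at the frequencies reported for pancreatic cancer |

Regulator genes are `Normal(μ_g + Δ·cluster, 1)` with gene baselines
`μ_g ~ Normal(8, 1)` (a log2-expression scale); background genes are
`Normal(0, 1)`.  Survival times are `Exponential(λ·exp(lp))`; censoring is
administrative-uniform on `[0, c_max]`, with `c_max` solved by Brent's
method so the expected censoring fraction `mean[(1−e^{−r c})/(r c)]` equals
the target (empirically within ±0.05 for n ≥ 500).  One integer seed is
expanded into fixed per-component substreams
(`SeedSequence(seed, spawn_key=(k,))`, k = cluster/expression/batch/survival/
censor/mutation/cnv/clinical), so a config + seed pair reproduces every
table byte-for-byte and changing one component's draw count cannot shift
another component's stream.

**What the generator does not emulate:** negative-binomial count noise and
library-size variation, gene–gene correlation beyond the planted cluster
structure, segment-level copy number, informative censoring, and
subclonal/impure samples.  Passing tests therefore demonstrate correctness
of the estimators under a clean location-shift/PH world, not robustness to
the full messiness of real RNA-seq.

## Batch correction

`combat_adjust` implements the parametric empirical-Bayes location/scale
model.  Per gene g and batch i: standardize by the batch-size-weighted
grand mean α̂_g and the pooled **within-batch** residual variance σ̂²_g;
estimate batch-gene locations γ̂_ig and scales δ̂²_ig; put a
`Normal(γ̄_i, τ̄²_i)` prior on locations and an `Inverse-Gamma(λ_i, θ_i)`
prior on scales with method-of-moments hyperparameters; iterate the
conditional posterior means

    γ*_ig = (n_i τ̄² γ̂ + δ*² γ̄) / (n_i τ̄² + δ*²)
    δ*²_ig = (θ + ½ Σ_j (Z_ijg − γ*_ig)²) / (n_i/2 + λ − 1)

until max|change| < 1e-6 (cap 100 iterations), then back-transform.  No
reference batch (cohorts are treated symmetrically) and no biological
covariates (cluster labels do not exist yet at correction time).  After
back-transformation every gene is re-anchored to its original overall mean:
batch correction moves batches relative to one another, never the grand
location.  A single batch is a no-op.  Note the procedure is a *contraction*
rather than exactly idempotent — a second application still shrinks
noise-level batch deviations (as the standard R implementation does) — and
the suite tests exactly that.

## Consensus clustering and model selection

Genes are z-scored (so regulator scale differences do not dominate the
metric), then for each of `reps` repetitions (default 1,000; the suite and
the acceptance script use 100, which is already stable at these sizes) a
fraction `subsample` (default 0.8) of samples is drawn without replacement
and Ward-clustered on Euclidean distance at each k.  The consensus matrix
entry is co-cluster count / co-sample count; final labels at each k come
from average-linkage clustering of 1 − consensus.  k is chosen by **PAC**
(fraction of off-diagonal consensus entries in (0.1, 0.9); ties go to the
smaller k), with the consensus-CDF Δ-area reported as a secondary
diagnostic and an `unstable` flag when even the best PAC exceeds 0.5.
Cluster "A" is the better-survival cluster when clinical data are supplied
(KM median ordering), otherwise the larger one.

A subtlety the tests encode: when three well-separated clusters are
*collinear*, the k = 2 solution is also perfectly resampling-stable (Ward
always merges the same adjacent pair), so PAC ties at zero and the smaller
k wins.  PAC discriminates k = 3 only when the k = 2 merge is genuinely
ambiguous, e.g. equidistant cluster centres with a smaller subsample
fraction.

## Single-sample enrichment

`ssgsea` ranks genes within each sample (average ranks on ties; the rank
statistic is the descending rank value, so scores depend only on ranks and
are invariant to monotone transforms).  With weights `|r|^α` (default
α = 0.25):

    ES = Σ_i [ P_in(i) − P_out(i) ]

where `P_in` is the weighted in-set running ECDF (normalized to 1 over the
set) and `P_out` the unweighted out-of-set running ECDF.  Optional
normalization divides the whole score matrix by its max − min range.  The
`gsva` variant computes a Gaussian-kernel CDF per gene across samples
(bandwidth = SD/4), re-ranks per sample on the symmetric statistic
`|n/2 − rank|`, and takes the signed maximum deviation of the same walk.
ssGSEA is the default for both immune and pathway scoring; the GSVA variant
exists so kernel-CDF-based activity profiles can be produced when wanted.
Sets are intersected with the matrix; the minimum post-intersection set
size is 1 by default (a single-gene set is a legitimate, if noisy, score)
and configurable upward.

## The m6Ascore

1. **Moderated t**: per-gene pooled variance s²_g (d = n₁+n₂−2 df) is
   shrunk to s̃²_g = (d₀s₀² + d s²_g)/(d₀+d); the prior (d₀, s₀²) is fitted
   by method of moments on log s²_g (digamma/trigamma matching, Newton
   trigamma inverse).  The moderated t has d₀+d df.  `d0_override=0`
   recovers the ordinary pooled t exactly (tested to 1e-10).
2. **DEG filter**: adj_p < 0.05 (Benjamini–Hochberg) AND |log2FC| > 0.5,
   both strict, matching the thresholds the score was defined with.
3. **Random-forest redundancy removal**: bagged CART trees (bootstrap per
   tree, √p features per split; default 500 trees), importance = mean
   decrease in out-of-bag accuracy under per-feature permutation of the
   OOB rows — the `randomForest::meandecreaseaccuracy` semantics.  Genes
   with positive importance are kept by default (`top_n` available).  Note
   permutation importance does *not* remove duplicated informative genes:
   both copies retain positive importance (tested, documented).
4. **Survival filter**: univariate Cox per gene on *continuous* expression;
   keep p < 0.05.
5. **Sign partition**: X = {β̂ > 0}, Y = {β̂ < 0}; β̂ = 0 exactly is treated
   as degenerate input and raises.  Y = ∅ is allowed (score reduces to
   scale(ΣX)).
6. **Score**: raw_j = Σ_X e_gj − Σ_Y e_gj on raw (not per-gene z-scored)
   expression, matching the defining formula; a flag enables per-gene
   standardization first.  The score is z-scaled with the *training*
   cohort's mean and n−1 SD, which are stored so external cohorts are
   scored on the same scale.  An optional PCA mode replaces the raw sum
   with the sign-aligned first principal-component projection of the
   signature genes (offered because the score is sometimes described that
   way; the sum formula is primary).
7. **Median split**: score > median → high, ≤ median → low (ties to low,
   deterministic); the median is stored for application cohorts.

`M6aScoreModel` wraps steps 1–7 statsmodels-style: construct from data,
`fit(seed)` returns an `M6aScoreResults` with the DE table, importance
ranking, the fitted `SignatureModel` (X, Y, β̂s, scale parameters, median),
per-sample scores/groups, `summary()`, `survival_contrast()` (log-rank +
Cox HR of high vs low) and `predict(new_expr)`.

## Statistical backend

Cox PH fits use the Newton–Raphson partial-likelihood maximizer with Efron
tie handling (lifelines), Wald CIs `exp(β̂ ± 1.96·SE)`; the suite
cross-checks against an independent single-covariate Newton solver and a
Breslow-ties implementation on tie-free data, where the three coincide.
KM is the product-limit estimator; the log-rank test is the k-sample
chi-square.  Rank-sum tests are exact for n₁+n₂ ≤ 20 without ties, else
normal approximation with tie and continuity correction (the two-sided p at
the exact null centre is 1).  Fisher's exact test sums hypergeometric
probabilities ≤ the observed table's (verified exhaustively against full
enumeration for all tables with total ≤ 12).  Multiple testing is BH
throughout (configurable); all tests are two-sided.  AUC is
Mann–Whitney U/(n₁n₀) with ties counted ½.  The TIDE responder label for
ROC defaults to `tide_score < 0` (threshold configurable) since external
TIDE files carry a continuous score.

## Pipeline

`run_pipeline` sequences merge → EB correction → landscape → consensus
clustering → enrichment → signature → survival/associations from a single
YAML config with exactly one data source (files or simulation) and a
mandatory seed.  Every stage writes TSV/JSON; the manifest records
parameters, seed and SHA-256 checksums of every output, and a rerun with
the same config + seed is byte-identical.  On a stage failure the manifest
is still written with `complete: false` and the failing stage named.

## Problem sizes and known limitations

The test suite and acceptance script run consensus clustering at 100
repetitions, cohorts of 200–300 samples, and 500–600-replicate null
calibrations — sizes at which every planted parameter is comfortably
recovered and the whole suite completes in a few minutes on one CPU.
Limitations: the moderated-t prior assumes roughly exchangeable gene
variances; PAC-based k selection inherits the collinear-cluster caveat
above; the RF importance is unscaled (no division by its SD across trees);
and none of the survival machinery handles competing risks, interval
censoring, or time-varying effects.
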