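# Methods

`rxremit` implements a treatment-specific prediction pipeline for remission
in randomized two-arm antidepressant cohorts, together with a synthetic
cohort generator that provides ground truth for every stage. This note
records the statistical procedure, the concrete estimator choices made where
the design was open, the defaults and why, and what the synthetic
experiments do and do not demonstrate.

## Study design

A cohort of n participants randomized to drug A or drug B carries a feature
matrix X (SNP dosages coded 0/1/2 plus clinical/demographic variables) and a
binary remission outcome y, defined as an HRSD-17 total of 7 points or less.
The cohort is split once — 65% training / 35% validation, stratified by
outcome × drug — before any per-drug work; with 430 participants this gives
exactly 280/150 (the training size is round-half-up of n × 0.65, allocated
across strata by largest remainder so each stratum's split is off by at most
one participant). Per drug arm, strictly inside the training partition:

1. **Stability selection.** 20 repetitions of stratified 5-fold
   cross-validation (100 rounds). In each round, CAT scores and local false
   discovery rates are computed on the in-fold four-fifths; a feature is
   retained when its LFDR falls below 0.8 in more than half of the executed
   rounds ("more times than not" is read as strictly greater than R/2; a
   round whose in-fold part has one outcome class is skipped and removed
   from the denominator).
2. **Model fitting.** An elastic-net logistic model on the retained
   features, with (α, λ) tuned by repeated stratified cross-validation
   (default 5 folds × 100 repetitions) maximizing mean out-of-fold AUC.
3. **Threshold.** The classification threshold maximizes Youden's
   J = sensitivity + specificity − 1 on training predictions and is frozen
   into the exported model. This is a documented assumption: sensitivity and
   specificity on validation data depend on it, and no standard rule is
   implied by the reporting format it reproduces.

Each frozen model is then evaluated on the same-drug validation partition
(external validation) and, without refitting, on the other drug's validation
partition (cross-drug specificity). The four resulting analysis cells —
same-drug ×2, cross-drug ×2 — are the study's primary output.

## CAT scores

For feature k, the standardized mean difference is
δ_k = (x̄_{k,1} − x̄_{k,0}) / (m·s_k) with m = √(1/n₁ + 1/n₀) and s_k the
pooled within-group standard deviation. The correlation-adjusted t-score
vector is τ = R⁻¹ᐟ² δ with R = λI + (1−λ)R_emp, where R_emp is the
empirical correlation of the within-group residuals and λ the analytic
shrinkage intensity

λ = clamp( Σ_{k<l} V̂ar(r_kl) / Σ_{k<l} r_kl², 0, 1 ),

with V̂ar(r_kl) the empirical variance of the per-observation products of
standardized residuals scaled by n/(n−1)³. The inverse square root is
applied through the SVD of the (unit-norm) residual matrix, so cost is
O(p·n²) and the p × p matrix is never materialized; at λ = 0 with
rank-deficient R_emp the component of δ outside the range of R_emp is
dropped (pseudo-inverse square root). Constant features receive score 0 and
a flag; otherwise s_k is floored at 10⁻⁸ × median(s) so a within-group
constant but between-group varying feature (a perfect separator) yields a
very large score rather than a division failure. Genetic and clinical
features are scored jointly in one matrix.

## Local false discovery rate

Scores are modelled as a two-component mixture
f(s) = η₀·f₀(s) + (1−η₀)·f₁(s). The null scale is the larger of a central
and a shoulder estimate, σ₀ = max(median|s|/Φ⁻¹(0.75), q₉₀|s|/Φ⁻¹(0.95)):
decorrelation leaves mildly heterogeneous per-direction scales, and a
purely central σ₀ then under-covers the shoulders so the whole moderate
tail of a null score set is spuriously flagged, while with few true signals
the 90% quantile remains null-dominated and costs essentially no power. The
marginal f̂ is a Gaussian kernel density estimate with Silverman
bandwidth h. Because f̂ is the data convolved with
the kernel, the null density used in the ratio is convolved with the same
kernel (scale √(σ₀² + h²)); without this, a pure-null score set would get
lfdr ≈ 0.85–0.9 purely from kernel smoothing of the mode. The null
proportion is η₀ = min(1, f̂(0)/f₀(0)), and
lfdr_k = clamp(η₀·f₀(s_k)/f̂(s_k), 0, 1), cleaned up to be non-increasing
in |s| by isotonic regression. At least 50 scores are required; an
all-equal score vector returns lfdr ≡ 1 with a warning. The contract of
this stage is behavioural — calibration under the null and power under
planted effects — not numeric replication of any particular library.

## Elastic-net logistic regression

On internally standardized features, the fit minimizes

(1/n) Σᵢ [log(1+exp(ηᵢ)) − yᵢηᵢ] + λ(α‖β‖₁ + (1−α)/2‖β‖₂²)

with an unpenalized intercept, by cyclic coordinate descent. Updates use
the exact coordinate curvature; if a sweep ever increases the objective the
solver switches to the ¼ curvature bound, whose updates minimize a true
majorizer, making the per-sweep objective non-increasing by construction.
Convergence is declared when the objective changes by less than 10⁻¹⁰
between sweeps (tighter than needed for prediction, so that the λ = 0 fit
matches an unpenalized maximum-likelihood fit to 10⁻⁴ and fitted zeros pass
the KKT check |(1/n)x_kᵀ(y−p)| ≤ λα + 10⁻⁶). Coefficients are
de-standardized to the raw feature scale for reporting; exported models
carry both the per-unit and per-SD scalings, since either may be the one a
reader expects, along with odds ratios, standardization constants,
hyperparameters and provenance, under a versioned JSON schema that
round-trips predictions exactly.

Tuning evaluates a per-α path of 10 λ values log-spaced over four decades
down from λ_max (the smallest penalty that zeroes every coefficient),
warm-started strong-to-weak, over α ∈ {0.1, 0.55, 1.0} by default. The
tuning metric is mean out-of-fold AUC; ties are broken toward larger λ and
then larger α (parsimony / stronger regularization). An empty retained set
degrades to an intercept-only model with a warning, so the pipeline is
total on null data.

## Evaluation

AUC is the Mann-Whitney probability (ties count ½), identical to
trapezoidal integration of the empirical ROC. Its 95% CI and the two-sided
test against AUC = 0.5 use DeLong placement-value variance with a Wald
interval truncated to [0, 1]; zero variance (perfect separation) collapses
the CI to a point and flags the report. Nagelkerke pseudo-R² is the
Cox-Snell ratio R²_CS = 1 − exp(2(L₀−L₁)/n) rescaled by its maximum
1 − exp(2L₀/n) and clamped to [0, 1]; on validation data the intercept-only
null L₀ is refitted to the evaluated labels (configurable in principle; an
anti-predictive model clamps to 0 rather than reporting a negative value).

## Synthetic cohorts

The generator emulates the structure of a two-drug pharmacogenetic trial:

- **Genotypes.** Each SNP draws MAF ~ Uniform(maf_range) (default
  (0.05, 0.5), above the 0.01 QC threshold by construction). Blocks of
  `ld_block_size` adjacent SNPs (default 10) share a latent AR(1) Gaussian
  with neighbour correlation `ld_rho` (default 0.5); each latent variable
  is thresholded at the Hardy-Weinberg quantiles P(0) = (1−MAF)²,
  P(1) = 2·MAF(1−MAF), P(2) = MAF². The implied dosage correlation is
  computable by bivariate-normal integration, which the tests use as an
  exact oracle. Thresholded AR(1) latents were chosen over haplotype
  copying for reproducibility and integrability; they produce blocky,
  stationary LD, not the long-range irregular LD of real genomes.
- **Clinical variables.** A cycle of 0–4 ordinal items (binomial),
  yes/no items (Bernoulli) and age/BMI-like continuous measurements
  (normal), each with its declared type, admissible levels and moments in
  the feature metadata so imputation rounding and sampling laws are
  testable.
- **Outcomes.** Per participant, η = intercept_d + Σ β_k x_k over the
  assigned drug's causal set. Binary mode draws remission ~
  Bernoulli(logistic(η)). HRSD mode draws an integer total in [0, 52],
  monotone non-increasing in η for a fixed uniform draw, with
  P(total ≤ 7) = logistic(η) by construction — so dichotomising at ≤ 7
  recovers exactly the same remission law, exercising the outcome
  derivation with known prevalence. Intercepts may be given as the literal
  `"center"`, which sets them to −Σ β_k E[x_k] for ≈ 50% prevalence; no
  per-drug remission prevalence is available to emulate, so this default is
  arbitrary and chosen only to keep both outcome classes well populated.
- **Missingness.** MCAR only, by default confined to clinical columns
  (genotypes after QC are essentially complete in this setting);
  outcome and drug labels are never masked. Informative missingness is out
  of scope, so the imputation stage is validated only under MCAR.
- **Randomization and seeding.** Drug allocation is a balanced permutation
  independent of all features. One global seed drives a `SeedSequence`
  spawned in fixed order (genotypes, clinical, drug, outcome, missingness),
  so cohorts are bit-reproducible; the pipeline spawns per-stage seeds the
  same way (selection and tuning per drug, in drug order).

`causal_maf_range` optionally draws causal-SNP MAFs from a narrower range.
The power studies in the acceptance suite plant causal variants among
common SNPs (MAF in (0.2, 0.5)): a per-allele odds ratio contributes
outcome variance β²·2·MAF(1−MAF), so at OR 1.8 a rare variant is nearly
undetectable at trial-scale n and the interesting regime — can the pipeline
find and use detectable drug-specific signals — requires common causal
variants.

## Preprocessing choices

- "LD over 0.8" is interpreted as squared Pearson correlation (r²) between
  dosage vectors, pruned by a greedy left-to-right scan against retained
  columns within a 50-column window (input order stands in for genomic
  position). The earlier (left-most) member of a correlated group is kept.
  Both the measure and the window are configurable; with r instead of r²
  the retained set would generally be smaller.
- MAF uses a strict inequality (> 0.01, folded to ≤ 0.5 over non-missing
  entries); completeness is non-strict (≥ 0.99). Filters commute on
  complete data.
- Bagged-tree imputation: 25 trees per target column (the method class
  prescribes no ensemble size; 25 is a conventional bagging default), each
  fit on a bootstrap resample of the rows observed in that column, with all
  other columns — mean-/mode-filled — as predictors; continuous targets take
  the ensemble mean, categorical targets the plurality vote with ties to the
  smaller value; imputed ordinal/binary values are then snapped to the
  nearest admissible level (ties toward the smaller). Observed cells are
  never altered.
- Residual genotype missingness after QC is completed by column mode.

## Problem sizes in the test suite

The acceptance experiments run the full pipeline at: null calibration,
10 cohorts of 560 participants (280 per arm) × 500 SNPs with no effects;
signal recovery and drug specificity, 10 cohorts of 2,000 participants ×
500 SNPs with 10 common causal SNPs per drug at per-allele OR 1.8 in
disjoint LD blocks and disjoint sets per drug, tuning at 5–10 repetitions
(the 100-repetition default is the study configuration; the reduced counts
are the suite's chosen problem size and change selection variance, not
bias); DeLong coverage, 500 replicates of a binormal AUC-0.77 model at
n = 150; determinism, a byte-level comparison of two complete study runs.
Chance-level AUC uses 20 replicates of n = 10,000.

## Known limitations

- The generator has no population structure, relatedness, genotyping error,
  Hardy-Weinberg violations or MNAR missingness; passing tests say nothing
  about robustness to those. Real-cohort results additionally depend on
  genome-wide imputation and sample QC, which are out of scope.
- The LFDR estimator is a concrete kernel-based choice; other null/marginal
  estimators would give somewhat different retained sets at the same 0.8
  threshold (which is deliberately liberal and provides no FDR guarantee).
- The stability-selection majority rule and the Youden threshold rule are
  documented interpretations where no rule was specified.
- Cross-drug evaluation reuses the model's frozen training threshold; with
  badly miscalibrated probabilities on the other arm, sensitivity and
  specificity can both sit far from their same-drug values even when AUC is
  near 0.5.
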