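# Methods

`exoscreen` implements a machine-learning screening strategy for diagnostic
biomarker panels in case/control expression cohorts, of the kind used to
search blood-exosome RNA profiles for a small-cell lung cancer (SCLC)
signature. This note documents the statistical model behind each stage, the
defaults and why they were chosen, what the synthetic cohorts do and do not
emulate, and the numerical conventions.

## Pipeline overview

Given a feature-by-sample count matrix `K`, sample labels (case/control) and
per-feature RNA types (mRNA / lncRNA / circRNA):

1. **Quality filtering.** Keep features non-zero in ≥ 80% of samples *and*
   with counts ≥ 5 in ≥ 10% of samples. Filtering precedes normalization,
   so library sizes are computed on the filtered matrix.
2. **Normalization.** `x = log2(count / L_j · 10⁶ + 1)` with effective
   library size `L_j` either the column total (default, deterministic) or
   the column total rescaled by a trimmed-mean-of-M-values factor
   (`trimmed-mean`; M-trim 30%, A-trim 5%, zero-count features excluded).
3. **Stratum harmonization.** RNA type is a *feature-level* technical
   stratum, not a sample batch, so the batch adjustment is defined over
   features: per-feature mean expression is standardized against stratum
   location/scale estimates — shrunk toward the cross-stratum values with
   empirical-Bayes weight `n_s / (n_s + λ)`, λ = 2 — and re-expressed
   against the grand location and the pooled within-stratum scale. Each
   feature is shifted by one constant, so case/control contrasts within a
   feature are untouched, and reapplying the adjustment is a near no-op.
4. **Differential expression.** Per feature, counts follow a negative
   binomial with `log μ_ij = β₀ + β₁·case_j + log s_j`, where `s_j` are
   median-of-ratios size factors and the dispersion α is a per-feature
   method-of-moments estimate on size-factor-normalized counts (computed
   within groups so the case/control shift does not inflate it; floored at
   10⁻⁸, so α → 0 recovers the Poisson GLM). β is fit by Fisher scoring,
   vectorized across features; the Wald statistic `β₁/se(β₁)` gets a
   two-sided normal p-value and Benjamini–Hochberg adjustment. Candidates
   must pass all three gates strictly: padj < 0.05, |log2FC| > 1.2, mean
   normalized expression > 50.
5. **Stability selection.** Three selectors on 20 stratified 80% subsamples:
   L1-logistic (penalty chosen by cross-validated log-loss over a grid of
   7 C values, 10⁻⁴…10²; selected = non-zero coefficients), random forest
   (500 trees; selected = top-20 by mean impurity decrease) and SVM-RFE
   (linear SVM, rank by squared weight, drop the lowest 10% per round;
   selected = last 20 survivors). Stability = exact fraction of iterations
   selected; a feature is consensus-flagged when stability ≥ 0.5 under
   *every* selector.
6. **Nested cross-validation.** Outer stratified 10-fold; inside each outer
   training partition (90%), the DE gate *and* the stability/consensus
   selection are recomputed from that partition's counts, an RBF-SVM is
   tuned by inner stratified 5-fold grid search (C ∈ {0.1, 1, 10, 100},
   γ ∈ {10⁻³, 10⁻², 10⁻¹, 1/d}) maximizing mean inner-fold AUC, and SMOTE
   (k = 5) balances classes inside training splits only. The *consistency
   score* (x/10) counts outer folds whose training data consensus-flag a
   feature; the final panel orders consensus features by (consistency desc,
   mean stability desc, adjusted p asc).
7. **Evaluation and calibration.** Probability scores come from a
   Platt-style sigmoid fit on the training-partition margins (fit on the
   original, unbalanced samples so probabilities reflect true prevalence).
   The operating threshold is Youden-optimal on the training partition and
   applied unchanged to the held-out 10%. AUC confidence intervals use the
   t-distribution over the 10 outer-fold AUCs. Calibration of the pooled
   held-out probabilities: Hosmer–Lemeshow over risk deciles, Brier score,
   and calibration slope/intercept from a logistic fit on logit(p).
8. **Validation.** External cohorts are scored with linear models
   (linear SVM, logistic regression, LDA) under stratified CV (folds capped
   by the minority class); panel members missing from the validation
   platform are dropped with a warning. Cross-cancer specificity either
   retrains per cohort (default) or transfers a frozen reference model.
   Enrichment is an upper-tail hypergeometric test against user-supplied
   GMT sets, BH-corrected.

## Synthetic cohorts

The generator emulates the structure of a public blood-exosome compendium:
negative-binomial counts (`var = μ + αμ²`) with lognormal baseline
abundances (median 100, σ = 1.5 — straddling the mean > 50 gate), gamma
dispersions (mean 0.2, typical bulk-RNA overdispersion), lognormal library
sizes (σ = 0.35), RNA-type mixture ≈ 0.22/0.09/0.69 (circRNA-dominated),
per-stratum multiplicative offsets of 2^±0.5 (mRNA/lncRNA vs circRNA), and
heavy class imbalance (111 cases vs 362 controls by default). Planted
biomarkers are down-regulated in cases by log2FC −3.80/−3.43/−3.33 by
default and are drawn from a higher-abundance lognormal (median 1000,
σ = 0.5): a marker suppressed ~13-fold in cases can only clear both the
prevalence filter and the abundance gate if its control-group abundance is
in the hundreds, which is the regime reported biomarker panels occupy.

Not emulated: read-level structure (FASTQ), circRNA back-splice junctions,
exosome isolation noise, sample-level batches, correlated co-expression
modules, or composition effects beyond library size. Passing tests
therefore demonstrate correctness of the statistical machinery and
recoverability of planted signals under realistic marginal distributions —
not performance on any real cohort.

## Design choices where the design was open

- **Per-fold candidate gate.** A DE gate computed once on the full cohort
  and reused inside cross-validation leaks held-out labels into selection
  and inflates null AUC well above chance (the classic selection-bias
  effect). `run_nested` therefore recomputes DE inside every outer training
  partition; the vectorized NB fit makes this affordable (< 1 s per fold at
  2,000 features). When the within-fold gate yields fewer candidates than
  the panel needs, it is topped up by adjusted-p rank (documented fallback,
  mainly relevant on null data).
- **Stability perturbation** is stratified 80% subsampling without
  replacement; the iteration count (20) is the protocol's, the subsampling
  scheme is this package's documented choice.
- **Comprehensive score** for the panel-size sweep (k = 2…10) is the
  unweighted mean of AUC, sensitivity and specificity of the pooled
  held-out predictions; configurable.
- **Hosmer–Lemeshow degrees of freedom**: `df = bins − 2` by default (the
  convention when the probabilities come from a model fitted to the same
  data); `df_mode="external"` uses `df = bins`, the correct reference when
  probabilities are produced independently of the evaluated outcomes — the
  calibrated-simulation type-I-error property holds under that mode.
  Equal-frequency decile bins; ties share the lower bin; bins with expected
  events < 1 merge into a neighbor.
- **Threshold rule**: Youden on training, frozen for the test partition —
  chosen to avoid test-set threshold leakage; headline sensitivity and
  specificity depend on this convention.
- **Cross-cohort specificity**: retraining per cohort is the default;
  `transfer` mode (train once on a reference cohort, apply frozen) is also
  provided, since published cross-cancer comparisons rarely state which was
  used.

## Numerical conventions and degenerate inputs

Log fold changes are estimated in natural log and reported in log2. Fisher
scoring clips the linear predictor to ±30 (bounding fold changes when a
group is all-zero) and iterates on the not-yet-converged feature set to a
step tolerance of 10⁻⁸. All-zero features report log2FC 0, p = 1, and a
flag. Size factors fall back to positive-count-only medians when no feature
is positive everywhere. Probabilities are clipped to [10⁻⁶, 1 − 10⁻⁶]
before logits; perfect separation in the calibration slope is detected
(non-overlapping score ranges) and flagged rather than raised. SMOTE
requires ≥ 2 minority samples and caps k at the minority size minus one.
Stability and consistency scores are exact rational counts. All stochastic
stages take explicit integer seeds; identical seeds give bit-identical
outputs, which the run manifest verifies by checksum.

## Problem sizes used by the test suite

The acceptance properties run at the study scale (111/362 samples, 2,000
features, 10 outer folds, 20 stability iterations, 20 replicates); unit and
property tests use compact cohorts (150–500 samples-by-features) chosen so
the full suite completes on a single CPU in well under half an hour. The
end-to-end determinism check runs a 500-feature, 40/80-sample pipeline
twice and compares manifests.

## Known limitations

- The NB dispersion estimator is method-of-moments without shrinkage;
  p-values at very small sample sizes are approximate (Wald/normal).
- Harmonization removes stratum-level location/scale structure only; it
  cannot correct feature-specific technical effects.
- SMOTE interpolates in the normalized expression space; with very few
  minority samples the synthetic points add little diversity.
- The consensus rule (stability ≥ 0.5 under every selector) is a sharp
  threshold; panels near the boundary can change membership across seeds.
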