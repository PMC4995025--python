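# Methods

## Model and estimators

### Genetic score and calibration

The instrument is a weighted allele score over independent (LD-pruned)
biallelic SNPs, GS_j = Σᵢ βᵢ d_ij, with external per-allele exposure weights
βᵢ (kg/m² per effect allele) and dosages d_ij ∈ [0, 2]. Because external
weights carry an arbitrary overall scale, the score is mapped to exposure
units by OLS of observed BMI on GS *among controls only*:
BMI-GS = β₀ + β₁·GS. Controls only, because case BMI in case-control studies
is typically measured after diagnosis and contaminated by reverse causation;
the fitted line is applied unchanged to cases. The calibrated score is a
linear transform of GS (correlation 1), so per-unit logistic coefficients on
it can be rescaled freely (reported per 5 kg/m²). The fraction of exposure
variance the score explains is the regression R² in the same controls.

Missing dosages (and panel SNPs absent from a dosage matrix) default to the
Hardy-Weinberg expectation 2·EAF, the usual dosage-expectation convention;
individuals with no observed dosages at all are excluded with a log entry
rather than silently imputed end to end.

### One-sample analysis

Case status is fit by maximum-likelihood logistic regression on the
calibrated score plus covariates. Two named adjustment profiles exist:
`basic` (age, eight genetic principal components, study site — the primary
model) and `extended` (adding age at menarche, parity, contraceptive use,
hormone-therapy use, breastfeeding, smoking). Wald CIs and p-values come from
the information matrix; effects are reported as exp(5β) per 5 kg/m².
Categorical analyses bin the calibrated score at configurable cutpoints
(default 25.5/26.0/26.5 kg/m², lowest bin as reference). The printed source
bins have a typographic gap (25.5–25.9 then 26.0–26.5); we implement
contiguous half-open intervals [25.5, 26.0), [26.0, 26.5), [26.5, ∞), which
is the only reading that partitions the line. The default reference cutpoint
is 25.5 and is exposed as configuration, since the source is internally
inconsistent about 25 versus 25.5.

Per-study estimation fits each study separately and combines by fixed-effects
inverse-variance meta-analysis; stratified analyses fit each stratum and test
heterogeneity by Cochran's Q on the stratum coefficients (for two strata this
is equivalent to the usual two-sample z-test on the difference). Strata below
100 individuals are skipped: below that size, separation and near-separation
make logistic estimates noise-dominated. Receptor-status strata (ER/PR) are
defined only for cases; stratified fits of such variables compare cases of a
subtype against the controls included in that subset.

### Two-sample analysis

For harmonized SNP i, the Wald ratio is β_YX = β_YG/β_XG with delta-method
standard error

    SE_YX = sqrt( S²_YG/β²_XG + S²_XG·β²_YG/β⁴_XG ).

This two-term form is the default; a `first_order` mode ignoring exposure
uncertainty (S_XG = 0) is provided because conventional IVW weighting uses
first-order weights, and the two are tested against each other. Instruments
with |β_XG|/S_XG < 2 are flagged weak but retained (the emulated design kept
all 84 instruments). Inverse-variance weighting combines ratios with weights
1/SE²; with first-order SEs this is algebraically the weighted regression of
β_YG on β_XG through the origin, an identity asserted in the tests at 1e-10.

Egger regression fits β_YG = a + b·β_XG with weights 1/S²_YG after orienting
every instrument to β_XG > 0 (sign-flipping β_YG accordingly). The intercept
a estimates the average directional pleiotropy; p-values are two-sided normal
(no small-sample t correction; the design has 84 instruments). With the
intercept constrained to zero the slope reproduces first-order IVW, which is
exposed as a cross-check mode.

### Harmonization

Outcome records are aligned to panel effect alleles by exact match, swap
(negate log-OR, reflect EAF), strand complement, or complement-plus-swap, in
that order; anything else is dropped as a mismatch with a warning. For
palindromic (A/T, G/C) variants strand cannot be inferred from allele labels:
the default policy drops them when either study's EAF lies in [0.42, 0.58]
and otherwise orients by matching minor-allele side; `drop-all` and `ignore`
(same-strand files) policies are available. Unmatched rsids are reported in a
structured way, never silently discarded, because outcome consortia routinely
lack a few instruments. Conversion of printed OR (95% CI) rows uses
z = 1.959964 (the unrounded 97.5% normal quantile) so re-derived cells are
reproducible to a pinned constant.

### Meta-analysis

Fixed effects only: the emulated analysis used a fixed-effects model, and
adding random-effects machinery would change the method surface; it is a
documented extension point. Cochran's Q with k−1 df quantifies
heterogeneity. Cross-consortium per-SNP combination applies the same formula
row-wise, passing through single-source SNPs flagged `unreplicated`. When
combining cells re-derived from numbers printed at two decimals, agreement is
expected at ±0.01 on the OR scale — input rounding, not estimator error,
dominates at that precision.

## Synthetic-data generator

The generator emulates the study design that motivated the package:

* **Panel.** EAFs uniform on (0.05, 0.95). Each SNP receives a share of the
  target score variance drawn uniformly in a three-fold band, giving
  per-allele effects b_i = sqrt(share_i·r²·σ²_BMI / 2f_i(1−f_i)), so the
  population score variance hits `r2_target` exactly. Shares are bounded away
  from zero deliberately: real instrument panels are ascertained at
  genome-wide significance, so near-zero effects do not occur. (An earlier
  half-normal draw produced unrealistically weak instruments whose estimated
  effects could cross zero; sign-orientation then attenuated the Egger
  intercept by ~30% — a real weak-instrument phenomenon, but not a property
  of significance-ascertained panels.) Default `r2_target` is 0.0123, the
  variance fraction the published score explained among consortium controls.
* **Cohort.** Genotypes Binomial(2, EAF) (HWE, hard calls by default; a
  fractional-dosage mode adds clipped Gaussian imputation noise). BMI = 26.4
  + centred score + 0.9·C + ε with C ~ N(0,1) a shared confounder and ε
  Gaussian, its variance set so total BMI SD is 4.5 kg/m² (typical for adult
  women). Case status ~ Bernoulli(expit(α + θ·BMI + 0.3·C + site effect)),
  with θ defaulting to ln(0.65)/5 per kg/m² and α solved by root-finding so
  the expected case fraction equals `n_cases_target/n_individuals` —
  operationally a balanced case-control sample. Covariates (age ~ N(57, 8²),
  8 standard-normal PCs, study site uniform over 5 sites with N(0, 0.1²)
  log-OR intercept shifts) and strata labels (65% postmenopausal; 50% HT use
  among postmenopausal; ER+ 78% and PR+ 70% among cases) are attached. Case
  BMI is masked by default. Default cohort size mirrors the emulated
  consortium (88,807 individuals, 46,325 cases).
* **Two-sample summary statistics.** Exposure and outcome studies are drawn
  independently (no sample overlap). Per-SNP exposure effects come from
  single-SNP OLS inside the exposure sample; per-SNP outcome log-ORs from
  single-SNP logistic fits inside the case-control outcome sample (an exact
  grouped Newton solver over the three dosage cells, verified against
  statsmodels). Optional directional pleiotropy adds direct SNP→outcome
  effects with mean `pleiotropy_mean` (SD `pleiotropy_sd`, default 0) to the
  outcome model. Default sizes mirror a large discovery GWAS (339,224) and
  the outcome consortium (16,003 cases / 41,335 controls).
* **Confounding is on by default** so that the naive BMI-outcome regression
  is biased while the genetic instruments remain valid — the scenario MR
  exists for. Its strength is a free, documented parameter; the real extent
  of BMI–breast-cancer confounding is unknown.
* **Randomness.** One root seed; every draw stage uses a fixed substream
  (`default_rng([seed, stage_code])`), so enlarging the panel does not
  perturb phenotype draws and identical configs are byte-reproducible.

What the generator does *not* emulate: LD between instruments (the panel is
defined as pruned at r² < 0.1), imputation uncertainty, population
stratification actually correlated with genotype (PCs are independent noise
here), age- or time-varying BMI effects, and case oversampling from a
low-prevalence population (the logistic intercept is solved instead). Tests
passing on this generator therefore show the estimators are correct and
calibrated under the assumed model — not that the assumptions hold in any
real cohort.

## Validation experiments and problem sizes

The published cohort-level estimates cannot be recomputed without private
individual-level consortium data, so `scoremr.validation` checks the
pipeline's statistical behaviour where the truth is known, at sizes chosen to
keep a full run at a few minutes on one CPU:

* coverage: 50 cohorts of 20,000 (half cases) — the 95% CI for OR per
  5 kg/m² should cover the generative 0.65 in ≥ 90% of seeds;
* IVW null calibration: 200 seeds, exposure n = 200,000, outcome
  10,000/10,000, θ = 0 — z-scores standard normal (KS);
* Egger recovery: same sizes with a 0.01 injected intercept — mean intercept
  within ±0.003;
* delta SE: 10⁶ Monte-Carlo ratio draws at (β_YG = −0.02, S_YG = 0.01,
  β_XG = 0.05, S_XG = 0.004) — delta/MC ratio within 5% (first-order regime).

The exposure-study size for the two-sample experiments (200,000 rather than
the 339,224 default) keeps mean instrument F ≈ 29, comfortably in the
strong-instrument regime where the delta expansion is accurate.

## Numerical choices and degenerate inputs

* Normal quantile pinned at `scipy.stats.norm.ppf(0.975)` = 1.959964;
  two-sided normal p-values throughout the summary-statistic estimators.
* Logistic fits: statsmodels Newton MLE; non-convergence and perfect
  separation surface as `DegenerateFitError` naming the offending fit rather
  than propagating raw optimizer states.
* Calibration requires ≥ 3 complete pairs and non-zero score variance;
  Cochran's Q requires k ≥ 2; Egger requires ≥ 3 usable instruments; Wald
  ratios refuse β_XG = 0; empty meta-analysis input is a domain error.
* Score bin boundaries belong to the bin above (left-closed intervals).
* Grouped logistic Newton: 40 iterations max, 1e-12 step tolerance, exact
  observed-information SEs; raises on single-class outcomes.

## Known limitations

* Fixed-effects meta-analysis only; no random-effects, weighted-median, or
  mode-based estimators, and no multivariable MR.
* No genome-build liftover, proxy-SNP lookup, or LD-aware operations.
* Egger regression inherits its usual caveats (InSIDE assumption, low power,
  sensitivity to instrument strength); the generator's ascertained panels are
  the favourable case.
* The one-sample model assumes the calibration line estimated in controls
  transfers to cases; selection on case status perturbs this slightly at
  strong effect sizes.
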