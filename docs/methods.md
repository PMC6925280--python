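# Methods

This note documents the models behind `metagrs`, the defaults that
matter, the synthetic data the tests run on, and the numerical choices
made where more than one convention is defensible.

## Component score construction

A component GRS for trait *k* is `sum_j x_ij alpha_jk` over the
variants that survive (i) greedy LD pruning and (ii) significance
thresholding of that trait's GWAS summary statistics.

*Pruning.* The sweep runs left to right in (chromosome, position)
order; a variant is kept only if its squared Pearson dosage
correlation with every already-kept variant within `window_kb`
(default 250 kb) is at most `r2_max`. When a pair violates the
ceiling, the earlier variant wins — a fixed, deterministic tie-break.
r² is computed on dosage columns (hard-call genotype correlation, with
per-variant mean imputation of missing calls), not haplotype LD, which
is the right scale for scores computed from hard calls. Pruning is
evaluated over a configurable grid of r² ceilings (default
{0.1, 0.2, 0.5, 0.8}); each candidate's standardized score enters a
Cox model on a tuning cohort with survival outcomes, and the candidate
with the largest |log HR| is kept, ties going to the sparser score.

*Thresholding.* Either `p <= cutoff` or Benjamini–Hochberg
`q < cutoff`; BH q-values are the standard step-up and are verified
against an exhaustive oracle in the tests.

*Standardization.* Scores are standardized to zero mean and unit SD
(denominator n−1) on a declared reference cohort; the transform is
stored with the score so the same units apply out of sample. The SD
convention only rescales gamma/sigma jointly and cancels in the
collapsed weights.

## Allele harmonization

Variant identity for all joins is (chromosome, position) with allele
reconciliation — rsIDs are carried but not trusted across sources.
For each positional match: same alleles pass through; swapped
effect/other alleles flip the sign of the effect (and the frequency to
1−EAF); a strand-complement match is complemented first.
Strand-ambiguous palindromic variants (A/T, C/G) are dropped, the
conservative default when strand cannot be resolved from alleles, and
unmatched rows are dropped with counts reported. QC filters remove
rows *strictly below* the INFO / MAF thresholds, so values exactly at
a threshold pass.

## Stacking and collapse

Standardized component scores enter an elastic-net logistic regression
of case status. Component coefficients are penalized; the intercept
and any covariates are not — penalizing confounders would bias the
component log-odds. The penalty grid crosses mixing values
{0.1, 0.5, 0.9} with 20 log-spaced strengths auto-scaled from the
maximal score–outcome covariance. Folds are stratified by case status
and derived from sample identifiers rather than row order, so refits
under permuted input are identical. For each grid point the held-out
predictions over the folds are pooled into a single AUC ("pooled"
rather than per-fold-mean, a documented and configurable choice since
cross-validated AUC is ambiguous between the two); the maximizing
penalty is refit on the full derivation data. The optimizer behind the
fit is statsmodels' elastic-net GLM with a per-coefficient penalty
vector.

The fitted stack collapses to `w_j = sum_k (gamma_k / sigma_k)
alpha_jk` over the union of component variants, with `alpha_jk = 0`
for SNPs missing from a component. Components must already share one
allele frame; a variant with conflicting frames raises an error rather
than being silently reconciled. The collapsed weights are emitted
unnormalized: the score defined by a weight table is only ever used
after standardization, so any positive scale factor is irrelevant, and
the dropped standardization means amount to one additive constant per
cohort. The collapse identity — collapsed-weight score equals the
gamma-weighted component sum up to that constant — is the module's
core contract and is asserted to 1e-8 on simulated cohorts.

## Survival evaluation

Age is the time scale: entry at assessment age, exit at event or
censoring age (administratively capped at 75 years), so every fit uses
delayed entry. Fits are stratified by sex, weighted by inverse
selection probability when the cohort came from a designed
oversampling, and reported with sandwich standard errors grouped by
individual. The fitting backend is lifelines; with delayed entry its
partial likelihood uses Breslow-type tie handling, which is immaterial
here because simulated event ages are continuous.

*Baseline hazard.* Breslow's estimator, computed per stratum at the
weighted covariate mean (covariates are centred before the baseline
pass, as in standard survival software), with a Poisson-type variance
`sum d_t / denom_t^2`. Predicted cumulative incidence is
`1 - exp(-H0(t) exp((x - xbar)'beta))`; its CI combines the baseline
variance and the robust covariance of beta on the log-cumulative-hazard
scale (delta method). Curves are flat past the last event age and a
warning is raised on extrapolation.

*Proportional hazards.* The global Grambsch–Therneau test with the
identity time transform, computed from Schoenfeld residuals against
delayed-entry risk sets (standard library residuals do not support
delayed entry). Null uniformity of its p-value is verified by
simulation.

*Concordance.* Harrell's C restricts comparable pairs to overlapping
at-risk windows: an event at age t is compared with subjects whose
window (entry, exit) covers t; score ties count 0.5. Small-cohort
values are verified against exhaustive pair enumeration. The CI uses
the between-event variability of per-event concordance fractions — a
jackknife-style approximation that ignores the correlation induced by
shared controls and should be read as indicative.

*Percentile-bin hazard ratios.* Bin membership by empirical score
quantiles enters one Cox fit as a categorical predictor with the
middle 45–55% bin as reference.

*Calibration.* Predictions from an event-enriched derivation model
are transferred to the target cohort by dividing the odds by the
derivation-to-target event-rate ratio (an intercept shift of
−log(ratio) on the logit scale, the standard transfer for logistic
absolute risk), then cut into deciles; per-decile observed proportions
carry exact binomial 95% intervals.

*Liability scale.* Observed-scale R² of a binary trait converts with
the linear threshold-model factor `K²(1−K)² / (z² P(1−P))`
(`z` the normal density at the prevalence threshold), reducing to
`K(1−K)/z²` at P = K; an ascertainment-corrected nonlinear variant
`C·R² / (1 + C·θ·R²)` is available behind a `method` switch since the
literature uses both. The factor is checked against a numerical
integration of the threshold model to 1e-6. Explained heritability is
the converted R² divided by each value of an h² grid (default
0.1–0.4, reflecting the plausible range for stroke liability).

## The synthetic cohort generator

The generator emulates the statistical structure the method assumes,
not any particular population's history.

*Genotypes.* Unphased hard calls from exchangeably correlated latent
normals, discretized at Hardy–Weinberg cut points. Variants within a
block share one MAF (tightly linked variants have matched
frequencies), and the shared-factor loading is compensated for
discretization attenuation so `within_block_r` approximates the dosage
correlation (capped where hard calls cannot reach it). There is no
recombination map, no phasing, and no population structure — enough
realism for dosage-r² pruning and scoring, nothing more.

*Architectures.* Per-variant effect vectors across the K traits are
drawn from a multivariate normal with the requested genetic
correlation matrix (Cholesky construction) and masked to causal
subsets that are nested prefixes of one shared permutation — so traits
with equal causal fractions share their causal set and the stated
correlations are realized rather than diluted by non-overlapping loci.
Genetic values are standardized on the cohort to variance h², with
independent N(0, 1−h²) environmental noise, so realized heritability
matches the specification by construction; per-allele effects are
rescaled to the same liability units.

*Summary statistics.* An external GWAS of n samples contributes
`alpha_hat = alpha + N(0, se)` with `se = 1/sqrt(2 n p (1−p))` and
two-sided Wald p-values, drawn independently of the target cohort
(no sample overlap).

*Risk factors.* SBP/DBP/BMI/LDL with first-assessment means and
spreads of a large middle-aged European cohort, smoking 10%, diabetes
4.7%, BP medication 20.5%, lipid medication 16.9%; medication
probability rises with the measured value. The derivation rules are:
+15 mm Hg SBP on BP medication, +1.5 mmol/L LDL on lipid-lowering
medication, and the expanded hypertension definition (medication, or
SBP > 140, or DBP > 90, or a hospital-record flag, all strict
inequalities).

*Survival.* Event ages from a Gompertz proportional-hazards model
`h(t) = b e^{ct} e^{eta}` (default b = 2.8e-6, c = 0.10 per year — an
age-rising hazard with ~5% cumulative baseline incidence by the
administrative cap at 75, enough events for the evaluation statistics
to be resolved while staying in a rare-disease regime). Entry ages are
Uniform(40, 69); sex enters the hazard as a male log-HR of 0.45,
mimicking higher male stroke incidence; events before entry are
flagged prevalent and excluded from incident analyses. The
derivation/validation split oversamples cases by a configurable factor
and attaches `1 / P(remaining in validation)` weights to validation
samples — the convention consumed by the weighted Cox fits.

What passing tests on this generator do **not** show: robustness to
genome-scale LD complexity, allele-frequency mismatch between GWAS and
target populations, population stratification, genotyping or
imputation error, competing risks, or time-varying risk factors.

## Experiment design choices

The end-to-end experiments (`metagrs.experiments`) fix these
conditions:

- *HR recovery:* 20 replicates of n = 50,000 with a standard-normal
  predictor at true HR 1.26 per SD — an effect size typical of a
  polygenic score for a heterogeneous disease — checking both the
  estimate and nominal CI coverage.
- *Stacking gain:* 20 replicates of a 4-trait architecture (disease
  trait plus a close outcome at genetic correlation 0.7 and two risk
  factors at 0.45/0.30), disease GWAS of n = 1000–2000 against
  risk-factor GWAS of n = 20,000. The comparison uses a case-control
  outcome (liability threshold at prevalence 0.10, split-half
  derivation/test at n = 8000) rather than incident survival status:
  at these cohort sizes the variation in entry age dominates
  event-status AUC and would drown the paired stack-vs-component
  comparison, and the stacking fit itself is a case-control logistic
  regression, so the binary design isolates exactly the step being
  tested.
- *Incidence consistency:* one n = 100,000 cohort; the model-based
  curve at the mean profile is compared with the Kaplan–Meier
  complement per sex at ages 60/70/75. The two estimands differ by a
  Jensen term of order `exp(beta²/2) − 1` (~0.2 percentage points
  here), which the 0.5-point band accommodates.
- *Calibration:* n = 50,000 logit-normal risks around ~5%, outcomes
  drawn from the predictions, rate ratio 1.

## Known limitations

- The concordance CI is approximate (see above); percentile-bin HRs
  for very small extreme bins inherit the instability of sparse Cox
  fits.
- The cumulative-incidence CI ignores covariance between the baseline
  hazard and beta; for profiles near the covariate mean the beta term
  dominates and the approximation is mild.
- `fit_cox` delegates to lifelines' delayed-entry path, which is
  O(slow) at very large n; fits at n = 10^5 take tens of seconds.
- The generator draws one MAF per LD block and exchangeable LD; it
  cannot represent fine-scale LD decay within a block.
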