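# Methods

## Cohort arm

### Domain rules

Enrolment exclusions drop, in order and with first-matching-reason logging:
records missing any liver test or any OGTT value; a history of hypertensive,
diabetic, cardiac, hepatobiliary or kidney disease; abnormally elevated
enzymes (ALT > 90, AST > 80, GGT > 90, ALP > 240 U/L — strictly above, so a
value at the bound is retained). The clinical-reference filter
(ALT > 45, AST > 40, GGT > 45, ALP > 120 U/L) is applied only in sensitivity
reruns. Filters are idempotent by construction.

GDM is diagnosed from the 75 g OGTT with inclusive cut-offs (fasting ≥ 5.1,
1-h ≥ 10, 2-h ≥ 8.5 mmol/L; any one suffices). Subtypes: i-IFG (fasting
only), i-IGT (any post-load value, fasting normal), b-GDM (both). Either
post-load value alone qualifies as i-IGT; the two post-load channels are not
required jointly. An incomplete OGTT yields *no* diagnosis — the record is
flagged and excluded, never silently counted as non-GDM.

Quartile binning uses the sample 25th/50th/75th percentiles with linear
interpolation; bins above Q1 are left-open/right-closed, so a value tied
with a cut point falls in the lower bin. This reproduces non-overlapping
integer bin reports (e.g. ALT 1–10 / 11–13 / 14–19 / 20–87 U/L) when the
data are integer-valued. Bins are reported as observed (min, max) ranges
together with the interpolated cut points.

### Models

All cohort models adjust for maternal age, first-trimester BMI, education
(ordinal integer 0–3), gravidity, parity, weight gain before the OGTT,
gestational age at measurement, and smoking and alcohol status (three-level
categorical with "unknown" kept as its own level). When the exposure is the
HSI — which contains BMI — BMI enters as its category
(<18.5 / 18.5–23.9 / 24.0–27.9 / ≥28 kg/m²) instead of a continuous term.

*Quartile logistic model.* Binomial GLM with logit link; odds ratios are
exp(coefficient) with Wald 95% CIs on the log scale (reported CIs are
symmetric on that scale; profile likelihood is not used). The linear-trend
p-value is the Wald test of a second model in which each woman carries her
quartile's median exposure value as a continuous covariate. A quartile cell
with zero cases or zero controls is quasi-separated; the affected contrast
is returned flagged with an infinite CI rather than crashing.

*Spline screening.* The biomarker–glucose dose–response is screened with a
restricted cubic spline in the truncated-power form, linear beyond the
boundary knots, knots at the 5th/35th/65th/95th percentiles (the standard
4-knot placement). Nonlinearity is the likelihood-ratio test of the
nonlinear spline terms against the plain linear term (χ², k−2 df). If
p ≥ 0.05 the linear model is retained; otherwise a single-breakpoint
segmented model is fitted: the breakpoint is profiled over a grid of
exposure percentiles (10th–90th), choosing the residual-sum-of-squares
minimiser, with continuity enforced through a hinge term and at least three
observations required on each side of a candidate break. A flat RSS profile
falls back to the linear fit with a warning. Fewer than 50 observations is
an error (the basis is unstable).

*Subtype model.* Multinomial logit with non-GDM as the reference; a subtype
with no cases is omitted with a warning. Continuous covariates are
centred/scaled inside the fit for Newton stability (the reported quartile
contrasts are invariant to this); a BFGS refit backs up the Newton solver.
With two categories the model coincides with the binary logistic model,
which the tests exploit as an internal consistency oracle.

*Crossover interaction.* The liver index and the lipid are dichotomised at
their sample medians (the cut is configurable — the split point is a design
choice, and medians give balanced cells). One logistic model with both main
effects, their product and the covariates yields the four joint-category
odds ratios against the low/low reference (the high/high cell is the
product of the mains and the interaction term by construction) and the
multiplicative interaction p-value (Wald test of the product term).
Additive-scale indices (RERI/AP/S) are out of scope.

*Baseline description.* Continuous variables as median (IQR) compared by
Mann-Whitney rank-sum; categorical as N (column %) by chi-square over all
levels; education compared by rank-sum on its ordinal codes.

## MR arm

Per-allele effects for the binary outcome are on the log-odds scale, so
causal estimates exponentiate to odds ratios per unit of exposure.

*Selection* keeps SNPs with p < 5×10⁻⁸ and MAF > 0.01, both strict, minus a
user-supplied exclusion list of known-pleiotropic variants (the stand-in
for a GWAS-catalog screen). *Clumping* is the standard greedy algorithm:
lowest p-value first as index, discarding unassigned SNPs on the same
chromosome within ±10,000 kb whose r² with the index exceeds 0.001; p-value
ties break lexicographically on rsid; pairs absent from the user-supplied
LD table count as r² = 0 with one logged warning (the engine takes a
pairwise r² table rather than bundling a reference panel). *Harmonization*
matches on rsid, sign-flips swapped allele pairs (eaf complemented), drops
palindromic SNPs (A/T, C/G) outright because strand cannot be resolved from
alleles alone, drops any other configuration as a mismatch, and drops SNPs
absent from the outcome study (no proxy search); every decision is logged.

*Estimators.* The Wald ratio uses the first-order delta-method SE
(`se_out/|β_exp|`); exposure uncertainty enters only through the
F-diagnostics, matching the reciprocal-outcome-variance weighting
convention. IVW is the weighted mean of the ratios, equivalent to
zero-intercept weighted regression of outcome on exposure effects with
weights 1/se_out²; the default SE is multiplicative random-effects (fixed
SE times √(Q/(m−1)), floored at 1 — robust under the heterogeneity typical
of many-instrument sets), with the fixed-effect SE kept in the diagnostics.
A single instrument reduces exactly to the Wald ratio. MR-Egger regresses
with a free intercept after orienting every SNP to β_exp ≥ 0; SEs use
multiplicative dispersion floored at 1 and a t reference with m−2 df; the
intercept's test is the directional-pleiotropy diagnostic. The weighted
median interpolates the inverse-variance-weighted cumulative distribution
of ordered ratios at weight 0.5; its SE is a seeded parametric bootstrap
(default 1000 draws). Multivariable MR is zero-intercept weighted
multivariable regression on the exposure-effect matrix; an all-zero
exposure column (no genetic signal) is dropped from the regression and
reported as unidentified, whereas genuine rank deficiency (e.g. duplicated
exposures) is an error.

*MR-PRESSO.* The global statistic is the weighted residual sum of squares
of each SNP against its leave-one-out IVW prediction; its null distribution
comes from seeded parametric draws of both β_exp and β_out around their
model-consistent expectations (default 10,000 draws; the empirical p is
floored at 1/n_sim, and a warning fires when the floor cannot resolve a
requested significance threshold). Per-SNP outlier p-values use each SNP's
own simulated residual distribution with Bonferroni correction (floored at
m/n_sim — n_sim must exceed m/α for detection to be possible). The
distortion test compares the shift in the IVW estimate after outlier
removal with the shifts produced by replacing the outliers with resampled
inliers.

## Synthetic-data generators

*Cohort.* Covariates follow first-trimester frequencies typical of a
Chinese pregnancy cohort (age ≈ 28 ± 4 truncated to 18–45; BMI log-normal
around 21 kg/m²; education 17/15/31/37%; parity-0 ≈ 68%). The eight
biomarkers (ALT, AST, GGT, ALP, TG, TC, LDL-C, HDL-C) are multivariate
log-normal with location/scale matched to published medians and IQRs (ALT
13 [10, 19] U/L etc.) and a positive-definite correlation matrix with
strong transaminase (0.7) and lipid-panel (TC–LDL 0.85) blocks. The three
OGTT channels are Gaussian (means 4.4/7.4/6.4, SDs 0.35/1.5/1.2 mmol/L)
with exchangeable noise correlation 0.5; their means are shifted by the
configured effects — per SD of log-biomarker in channel-SD units by
default, with a raw-scale linear option and a hinge term
coef·(x−t)₊^power for segmented (power 1) or J-shaped (power 2) truths —
plus small age and BMI effects. Default biomarker effects encode
transaminases acting only on post-load glucose and GGT/ALP also raising
fasting glucose. A shared intercept shift, found by bounded bisection, is
applied across channels so that the realised GDM prevalence (computed
through the package's own diagnosis) lands within 0.01 of the 18.2%
target; an unattainable target is an error. Lipids are set missing
completely at random for ≈ 52% of women (4,340 of 9,148 with lipid tests).
The generator does *not* emulate measurement error in the enzymes,
informative missingness, secular trends, or real covariate–biomarker
dependence (BMI is drawn independently of the enzymes), so passing tests
demonstrate correctness of the statistical machinery under a known truth,
not robustness to those real-data features. Because glucose is a
thresholded Gaussian rather than logistic in the predictors, logistic
model coefficients recover the generator's ordering and nulls exactly but
its magnitudes only approximately; calibration studies therefore use full
nulls, where size is exact.

*GWAS pair.* Per SNP: MAF ~ U(0.05, 0.5); true exposure effect
γ = γ_min + |N(0, 0.02)|, positive — the effect allele is the
exposure-increasing allele, as in a post-selection instrument set (this is
also what makes "directional" pleiotropy directional for IVW); sampling
SEs follow 1/√(2·maf·(1−maf)·n); β_exp ~ N(γ, se_exp);
β_out ~ N(θγ + α, se_out) with α the pleiotropy term applied to a
configured fraction of SNPs (balanced: mean zero; directional: mean 0.02).
Defaults mirror the study conditions: 166 instruments (the reported ALT
count), exposure n = 500,000, outcome n = 123,579 (5,687 cases + 117,892
controls), θ = 0.25 (OR ≈ 1.28), and γ scale 0.02 giving a mean
F-statistic near 80 (the reported ALT mean F is 79.4). LD is emitted as
exchangeable block-diagonal r² with blocks 50 Mb apart — the simplest
structure that exercises clumping; a configurable fraction of outcome rows
is reported on the opposite allele orientation to exercise harmonization.
Individual-level genotypes are never simulated; the InSIDE assumption
(α ⊥ γ) holds by construction.

## Validation studies and problem sizes

`gdmliver.validation` re-runs each analysis over replicates with child
seeds spawned from one generator (all below 2³¹). Problem sizes: IVW
recovery at 500 replicates (m=100, n_exp=300k, n_out=120k); Egger-vs-IVW
at 500 replicates with all instruments pleiotropic (mean 0.02);
weighted-median-vs-IVW at 200 replicates with 50% invalid instruments;
Q-test size at 500 replicates under its exact null (θ = 0 — with a nonzero
θ the ignored exposure-side uncertainty makes ratios slightly
heterogeneous by construction, which is a property of the estimand, not a
test defect); spline/trend/interaction sizes at 500 replicate cohorts of
n = 2,000/1,500/2,000 under full generator nulls; MR-PRESSO null at 200
replicates (500 simulation draws each) and spike-in detection (+10·SE) at
100 replicates with 2,000 draws. These sizes keep each study to seconds
while leaving Monte-Carlo noise well inside the tolerance bands the tests
assert.

## Known limitations

- The Wald-ratio SE ignores exposure-side uncertainty (NO Measurement
  Error assumption); with weak instruments the estimates attenuate — the
  mean-F warning at ≤ 10 flags this.
- The weighted-median bootstrap resamples summary statistics
  parametrically; it does not propagate LD between instruments (inputs are
  assumed clumped).
- The segmented model fits one breakpoint only and reports no CI for its
  location.
- The cohort models use complete-case analysis; glucose values are never
  imputed, and records missing lipids are retained everywhere except the
  interaction analysis.
- Real GWAS inputs must share rsids across studies; there is no positional
  matching or proxy lookup.
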