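# Methods

## Scope and design

`prsgxe` implements a pooled case-control gene–environment analysis:
a weighted polygenic risk score (PRS) in quartiles crossed with a binary
exposure (menopausal hormone therapy, MHT — any use, estrogen-only, or
combined estrogen-progestogen), covariate-adjusted logistic models for
the joint odds-ratio grid, interaction on the multiplicative and
additive scales, and 30-year absolute-risk projection. The package is
organised as plain functions returning result dataclasses that carry
coefficients, covariances and likelihoods (the statsmodels idiom), since
every downstream quantity — stratified ORs, RERI variance, bootstrap
CIs — is a function of the fitted coefficient vector and its covariance
rather than of predictions.

## Scoring and quartiles

The PRS is the inner product of effect-allele dosages (in [0, 2],
possibly fractional after imputation) with fixed external log-OR
weights; the package never re-estimates weights. Weight-table alignment
handles the case where a genotype source counts the non-effect allele:
the dosage reflection g → 2 − g is absorbed exactly by negating the
weight and adding 2w to a score offset, so aligned and manually recoded
scores agree to machine precision. Strand-ambiguous (A/T, C/G) variants
cannot be resolved from alleles alone; they are flagged and either kept
(with a warning) or dropped, by configuration.

Quartile cut points are the 25/50/75 percentiles, computed with linear
interpolation between order statistics, of the basis group's PRS.
The basis is the pooled controls by default — the usual convention in
case-control PRS work, since the control distribution approximates the
source population — with a switch to the pooled sample; study-specific
cutting is deliberately not a default because it changes the meaning of
the cell dummies across studies. Categories are the half-open intervals
(−∞, q25], (q25, q50], (q50, q75], (q75, ∞), so subjects outside the
basis group are always categorizable. An all-tied score is an error:
quartiles are undefined, not arbitrarily broken.

## Association models

All models are maximum-likelihood logistic regressions (Newton, relative
tolerance 1e-8, max 100 iterations; non-convergence, separation-induced
infinite SEs, and empty quartile × exposure cells are hard errors naming
the offending term, never silent). Adjustment is age (linear), BMI
(linear), study (unordered dummies, first level as reference) and three
principal-component scores (linear) — the minimal functional forms.
Each exposure variable is analysed complete-case, so the three MHT
analyses legitimately use different sample sizes; exclusion counts are
logged.

The joint grid comes from one saturated model with 7 cell dummies
((quartile × exposure) minus the (Q1, unexposed) referent). Stratified
presentations are computed from the fitted cells, not refitted: the
saturated parameterization makes the within-quartile exposure OR exactly
OR_k1/OR_k0 and the within-stratum quartile OR exactly OR_ke/OR_1e, with
log-scale variances from the cell covariance (the reference cell enters
as an exact zero). The trend test refits the stratum subset with the
quartile index (1–4) as a single numeric covariate and uses the Wald
statistic. Heterogeneity across studies uses Cochran's Q on
study-specific adjusted exposure log-ORs with fixed-effect
inverse-variance pooling.

## Interaction

*Multiplicative*: likelihood-ratio test comparing main effects (three
quartile dummies + exposure) against the model adding the three product
terms, identical covariates and subjects in both fits; χ² with 3 df.
The product-term model is a reparameterization of the saturated cell
model, and the tests assert the two have identical likelihood and
identical implied cell coefficients.

*Additive*: RERI_k = OR_k1 − OR_k0 − OR_01 + 1 per quartile k ∈ {2,3,4},
treating quartile membership and exposure as the two "exposures" with
(Q1, unexposed) as the doubly-unexposed referent. Odds ratios stand in
for risk ratios under the rare-disease approximation; this is stated
rather than corrected, because the measure is conventionally reported
directly from case-control ORs. The variance is first-order Delta
method: gradient (e^{β_k1}, −e^{β_k0}, −e^{β_01}) against the 3×3
coefficient covariance block; CI = RERI ± 1.96·SE and a two-sided normal
p on RERI/SE. A parametric-bootstrap check (10,000 multivariate-normal
coefficient draws) agrees with the Delta variance within 5% at realistic
covariance magnitudes.

## Absolute risk

The projector converts relative to absolute risk for a 50-year-old woman
over 30 years:

1. Age-group relative risks: the cell model refitted within age ≤60,
   61–70, >70 (stratified fits are the minimal reading of "age-specific"
   estimation; age remains a linear covariate within group).
2. Attributable proportion per age group by the case-distribution
   estimator AP = 1 − mean over cases of 1/RR(profile); with cases
   distributed proportionally to population share × RR this inverts
   exactly, and the suite checks the algebraic identity
   λ₀ · E_pop[RR] = composite incidence to 1e-10.
3. Baseline hazard λ₀(a) = I(a)(1 − AP_g(a)), with I(a) from an external
   age-banded incidence table (per 100,000 person-years, any contiguous
   banding covering 50–80; 5-year registry-style bands natively).
4. Annual discrete recursion with piecewise-constant hazards and the
   cause-specific competing-risk decomposition (see README formula);
   1-year steps are the default discretization of the continuous
   cause-specific formulation. In the constant-hazard, no-mortality
   limit it reduces to 1 − exp(−30λ) exactly, and on arbitrary tables it
   agrees with an individual-level microsimulation oracle within
   Monte-Carlo error.
5. Uncertainty: subjects resampled with replacement within case/control
   strata; RRs and APs re-estimated per replicate; CI = point ± 1.96 ×
   replicate SD by default (normal approximation — percentile CIs are
   unstable at B = 100 and are available as an option). Replicates with
   unfittable cells are dropped and counted; more than 20% dropped is an
   error. Risk differences (non-user minus user, per quartile) use the
   same resamples for both profiles, preserving their correlation in the
   bootstrap z-test; the published analyses do not state their
   difference test, so this choice is the package's own.

## Synthetic data

The generator emulates the structure the analysis assumes, with defaults
set to the published study conditions: 141 biallelic variants with MAF
uniform on [0.01, 0.5] under Hardy–Weinberg equilibrium; weights
N(0.08, 0.04²) (per-variant log-ORs of typical GWAS magnitude); five
studies with intercept offsets spanning ±0.3; any-MHT prevalence 35.2%;
mutually exclusive estrogen-only / estrogen-progestogen labels among
users with type information present for a fraction of users and
non-users chosen to reproduce the published type-information subset
sizes and within-subset exposure prevalences (28.2% and 21.9%); age
N(62, 8²) years, BMI N(27, 5²) kg/m², inert N(0, 1) PC scores; and a
default case-control draw of 11,519 cases / 16,967 controls.

Disease status is Bernoulli with logit = anchor + study offset +
covariate effects + the true (quartile × any-MHT) cell log-OR, where
quartiles are cut on the simulated population's own PRS. Default cell
truths follow the published any-MHT grid (quartile ORs 1.42/1.94/2.82,
exposure OR 0.75 in Q1, exposed cells 1.09/1.40/1.83, i.e. mildly
sub-multiplicative); the interaction increments are configurable, with
(0,0,0) giving exact multiplicativity and log(OR_k0 + OR_01 − 1) −
log(OR_k0) − log(OR_01) giving exact additive-scale nulls (true RERI 0).
The truth record stores the cell grid, the OR-scale RERI and the
log-scale increments separately, because additivity on one scale is
non-additivity on the other.

Exposure is assigned independently of genotype (the standard
gene–environment independence assumption of case-control interaction
analysis); a correlation knob shifts exposure probability along the PRS
for robustness experiments. Matching is not simulated — the analysis
pools with covariate adjustment, not conditional likelihood. The
population prevalence anchor defaults to 0.25 with a population of
80,000 so the default case-control draw is feasible at desk scale;
because sampling is retrospective within outcome strata, the anchor
shifts only the intercept and leaves every odds ratio, interaction
contrast and RERI unchanged, which the suite verifies by comparing
population and case-control fits. Rate tables default to synthetic
registry-like values (incidence 60→380, mortality 300→5,600 per 100,000
person-years across 5-year bands, ages 50–85).

What the generator does not emulate: imputation uncertainty and
genotyping error, linkage disequilibrium between panel variants, real
population stratification (PCs are pure noise), informative missingness
of MHT type (missingness is completely at random), and age/enrollment
matching. Passing tests therefore demonstrate correctness of the
estimators under the stated model, not robustness to those real-data
complications.

All randomness descends from one master seed through named
sub-streams (genotypes, covariates, exposure, disease, sampling,
bootstrap), so stages can be regenerated independently and every
pipeline output is byte-reproducible given the seed.

## Test problem sizes

The suite calibrates against simulation at sizes chosen to keep the
default run at a few minutes while leaving comfortable statistical
margins: parameter recovery on a 20,000-subject cohort (cell-OR SEs
≈ 0.05–0.07); type-I error of the multiplicative LRT and coverage of the
RERI CI on 500 replicates each of 2,500 cases / 2,500 controls drawn
from 12,000-person populations (binomial SE ≈ 1% on both rates); and a
2×10⁶-individual microsimulation for the risk projector. One caution
learned from the recovery experiments: all seven cell ORs share the
reference cell, so their estimation errors are positively correlated and
single-dataset deviations can look systematic; calibration claims in the
tests are therefore made over replicates, not single draws.

## Known limitations

- ORs are used as RR approximations in RERI and the risk projector;
  with the simulated prevalence anchor this is a modelling convention,
  not an approximation guarantee.
- The attributable-proportion step assumes the fitted profile RRs apply
  to the external incidence population.
- Bootstrap normal CIs can cross 0/100 before clipping at extreme B or
  tiny strata; percentile CIs are available but noisy at B = 100.
- Quartile misclassification near cut points (controls-basis vs
  population quantiles) slightly attenuates trend estimates in small
  samples; at the default sizes the effect is well below one SE.
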