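# Methods

## Scientific setting

`liabtwin` analyses classical-twin-design cohorts of children with binary
neurodevelopmental phenotypes (clinical and subclinical autism and ADHD) and
binary physical health conditions (epilepsy, headaches, atopic and
gastrointestinal conditions).  Monozygotic (MZ) co-twins share all segregating
DNA, same-sex dizygotic (DZ) co-twins on average half; contrasting MZ and DZ
resemblance therefore separates additive-genetic (A), shared-environment (C)
and nonshared-environment (E) sources of variance, and — in the bivariate
case — of covariance between a neurodevelopmental phenotype and a physical
condition.

## Liability-threshold model

Each binary trait is the indicator of a latent standard-normal liability
exceeding a threshold `t` with upper-tail area equal to the prevalence `K`.
All model fitting reduces to rectangle probabilities of multivariate normal
distributions over such thresholds:

* **2-D** rectangles use Genz's hybrid algorithm (Gauss–Legendre quadrature on
  `asin(r)` for |r| < 0.925, a tail-variable transformation above), with
  absolute error below 1e-13 — verified against adaptive 2-D quadrature of the
  density.
* **3–4-D** rectangles use Genz's separation-of-variables transform with a
  scrambled Sobol rule.  The scramble seed (20230421) and point count
  (2^13 for one-off queries, 2^12 inside the bivariate likelihood) are fixed,
  so every result is bit-for-bit reproducible; observed error at the default
  point count is ~1e-7.  Within one model fit the same Sobol points are reused
  across iterations, keeping the objective smooth for the simplex optimizer.
* Correlation matrices are Cholesky-factorized; near-singular matrices are
  eigenvalue-clipped at 1e-12, and matrices with an eigenvalue below −1e-8 are
  rejected with the offending eigenvalue in the message.

**Tetrachoric correlations** are full maximum likelihood: the correlation and
both thresholds are estimated jointly from the 2×2 table (Nelder–Mead on
(atanh r, t1, t2), parameter tolerance 1e-10), the convention of ordinal-data
structural equation modelling software.  |r| within 1e-6 of 1 is flagged as a
boundary solution (this also keeps the log-likelihood finite).  Standard
errors come from the observed information (central-difference Hessian), with
the delta method back from the atanh scale; for double-entered tables the
variance is rescaled to the number of pairs.  A zero margin (trait never or
always present) yields an explicitly flagged undefined estimate.

## Univariate ACE/AE/E fits

With no covariates the zygosity-wise 2×2 cross-twin tables are sufficient
statistics, so the fit maximizes the joint multinomial likelihood over the MZ
and DZ tables — identical to the rowwise likelihood but orders of magnitude
faster.  A single threshold is shared across zygosities and twins (sex and
age do not moderate thresholds in the core model).  Path coefficients (a, c)
are estimated and squared for reporting, enforcing nonnegative variance
shares; the implied correlations are rMZ = a²+c², rDZ = a²/2+c².  When the
ACE solution lands on the C = 0 boundary the AE refit is reported alongside
(`fit_with_boundary_refit`), matching the convention of printing C = 0 rather
than leaving the row blank.  Confidence intervals are 95% profile likelihood
(deviance crossing of the 1-df chi-square 95th percentile, bisection to 1e-5);
e² is profiled through an angle parameterization that keeps a²+c² on the
constraint.  Likelihood-ratio tests of AE and E against ACE use the
chi-square reference as-is; on the C = 0 boundary this is conservative, which
is accepted and documented rather than corrected.

ADE models, sex-limitation models and opposite-sex DZ pairs are out of scope;
opposite-sex pairs can be generated for descriptive tables only.

## Bivariate correlated-factors model

For a trait pair, each twin pair has 16 observable response patterns; per
zygosity these counts (`PairTraitTable4x4`) are the sufficient statistic.
Cell probabilities are 4-D rectangles under the implied correlation matrix

* within twin, cross trait: rPH = a1·a2·ra + c1·c2·rc + e1·e2·re,
* cross twin, within trait i: g·ai² + ci²,
* cross twin, cross trait: g·a1·a2·ra + c1·c2·rc, with g = 1 (MZ), ½ (DZ),

computed by Möbius inversion of the lower-orthant CDFs over the 16 coordinate
subsets (one 4-D and four 3-D Sobol evaluations, six 2-D and four 1-D closed
forms per likelihood evaluation).  The correlated-factors parameterization is
estimated directly (9 parameters; correlations on the atanh scale, paths
folded nonnegative); the mathematically equivalent Cholesky parameterization
is provided with exact maps in both directions, and tests verify identical
implied matrices and likelihoods.  Non-positive-semidefinite proposals are
eigenvalue-projected with a quadratic penalty so the optimizer is repelled
without discontinuities.

A **two-stage moment estimator** (tetrachorics on the collapsed double-entered
margins, then Falconer-style identities for the variance shares and the MZ/DZ
contrast of the cross-twin cross-trait correlation for the covariance split)
provides starting values, a fast cross-check, and the estimator used when only
printed correlations are available.  Full ML is the default for cohort data;
whether thresholds/paths should be fixed from univariate fits or re-estimated
jointly was an open choice — joint re-estimation is used because it is the
maximum-likelihood answer, and the two-stage mode covers the fixed variant.
Profile-likelihood intervals are available for ra, rc and re (nuisance
parameters re-optimized from a warm start with a bounded iteration budget).

`decompose_rph` splits rPH into (a1·a2·ra, c1·c2·rc, e1·e2·re); the genetic
share is the bivariate heritability.  Proportions are flagged undefined when
|rPH| < 1e-6.

## Associations

Odds ratios between phenotype groups and conditions come from a
population-averaged logistic model (statsmodels GEE, independence working
correlation) with pair-level robust variance; sex and age-group enter as
categorical adjustments.  A strictly conditional (within-pair) likelihood
would absorb pair-constant covariates and could not produce sex/age-adjusted
odds ratios, so the population-averaged estimator is used.  Complete
separation is flagged with an infinite-bound interval rather than failing
silently; |log OR| > 15 is treated as separation.  The multiple-comparison
threshold is alpha/m with m defaulting to the number of outcome conditions
(13 in the standard panel, giving 0.05/13 = 0.0038).

## Descriptives

Cross-twin (cross-trait) tables are double-entered — both (twin 1, twin 2)
orderings contribute — so estimates are invariant to the arbitrary within-pair
ordering; tetrachoric standard errors are corrected back to the number of
pairs.  Proband-wise cross-concordance follows the standard rule that every
affected individual is a proband (concordant pairs contribute twice).
Proportion intervals are Wilson score, chosen for its behaviour at the small
counts of rare conditions; outputs label the method.

## Synthetic cohorts

The generator emulates the statistical structure the models assume: per pair,
liabilities are drawn from the 2T×2T multivariate normal implied by the
correlated-factors paths (A correlated 1/0.5 across twins, C shared, E
twin-specific; cross-trait correlations ra/rc/re within components), then
dichotomized at prevalence thresholds.  Defaults follow the motivating
cohort: 4,767 MZ and 5,580 same-sex DZ pairs, age 9 vs 12 in proportion
8,125:2,222, even sex ratio.  Opposite-sex DZ pairs are off by default and
never enter twin-model stages.  Where the published record gives no
cross-trait C or E correlations, shipped example configurations set rc = re = 0
(or a single re calibrated to a stated rPH) and label them illustrative.

A-TAC item scores are emitted by a graded-response device: item
`u_i = loading·liability + sqrt(1−loading²)·eps_i` cut at tau1 < tau2 into
scores 0 / 0.5 / 1.  The defaults (loading 0.8, band width tau2−tau1 = 1.0)
are a generic moderate item reliability; tau1 is solved analytically (item
total distribution by convolution, liability integrated by Gauss–Hermite
quadrature) so that the population screen-positive rates equal 3.6% (autism
module, 17 items, cutoff 4.5) and 10.5% (ADHD module, 19 items, cutoff 6.0).
The emission model is a simulation device, not an estimate of real item
parameters: it reproduces marginal screen rates and monotonicity in
liability, but not item-level factor structure, differential item
functioning, or informant effects.  Individuals with any missing item are
excluded from subclinical classification (listwise), with the exclusion count
reported.  Subclinical groups include clinical cases by default; the
sensitivity variant zeroes subclinical flags for diagnosed individuals.

What passing simulation tests shows — and does not.  The generator draws from
exactly the model family the estimators assume, so recovery tests validate
the estimation machinery (identifiability, numerics, calibration), not
robustness to real-data violations such as assortative mating, non-additive
genetic variance, sex-limited paths, measurement error beyond item noise, or
diagnostic censoring in registry data.

## Problem sizes and numerical choices

Simulation-based checks use 20,000 pairs per zygosity for univariate recovery
(12 replicates per configuration), 50,000 per zygosity for bivariate
recovery, 200 replicates for LRT null calibration, and 40 replicates of a
13-outcome panel for the family-wise error check; these sizes give
Monte-Carlo error comfortably inside the assertion tolerances while keeping
the default suite brisk.  Optimizers are Nelder–Mead throughout (the
likelihoods are cheap, low-dimensional and not always smooth at variance
boundaries), with parameter tolerances 1e-9/1e-10 univariate and 1e-6
bivariate.  Cell probabilities are floored at 1e-12 before logging.

## Known limitations

* No ADE, sex-limitation, assortative-mating or direction-of-causation
  models; no more-than-bivariate decompositions.
* Chi-square reference for boundary LRTs is conservative.
* The two-stage bivariate estimator is not efficient; it is a cross-check and
  a printed-summary path, not the default for raw data.
* GEE odds ratios are population-averaged; they deliberately differ from a
  conditional within-pair estimand.
* Bivariate profile intervals re-optimize nuisances under an iteration
  budget; for publication-grade intervals raise the budget and point count.
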