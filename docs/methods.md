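# Methods

`kidbank` implements the psychometric workflow used to calibrate and
validate caregiver-report child-development item banks for population-level
measurement between birth and 71 months: graded-response IRT calibration
with a latent age regression, EAP scoring, marginal and age-conditional
reliability, differential-item-functioning (DIF) screening with a
partial-invariance sensitivity analysis, and age-adjusted validity analyses
with multiple imputation. This note records the models, the numerical
choices, and the places where the design was genuinely open.

## Measurement model

For child *i* and item *j* with K_j ordered response categories,

    Pr(Y_ij >= k | theta_i) = expit(alpha_j (theta_i - delta_jk)),  k = 1..K_j-1,

with Pr(Y >= 0) = 1 and Pr(Y >= K_j) = 0; category probabilities are the
telescoping differences of adjacent cumulative curves. Binary items reduce
exactly to the two-parameter logistic model. Ability carries a latent
regression on age:

    theta_i ~ N(x_i' gamma, 1),

where x_i is a natural cubic spline in age (interior knots at 12, 24, 36,
48, 60 months, boundary knots 0 and 71). Identification: the residual SD
is fixed at 1 and the spline design is centered so fitted prior means
average zero over the sample; the location and scale of the latent metric
are absorbed by the item parameters. Responses are 0-based; structural
missingness (age-ineligible items, closed-interval windows on integer
months) contributes nothing to the likelihood, which marginal maximum
likelihood handles without imputation.

## Estimation

Calibration is EM on a fixed rectangular quadrature grid: 101 equally
spaced nodes spanning [min_i mu_i - 6, max_i mu_i + 6], with per-child
normalized prior weights on the common grid (person-specific prior means
make shared Gauss-Hermite awkward; a wide common grid is simpler and can
be checked against a dense integrator — rectangular quadrature of
Gaussian-type integrands at node spacing <= 0.2 is accurate far beyond
the 1e-6 oracle tolerance used in the tests). The grid is rebuilt each
cycle from the current gamma.

The M-step maximizes the expected complete-data log-likelihood per item by
L-BFGS on an order-preserving reparameterization (log alpha; first
threshold free; log increments), with analytic gradients; gamma is updated
by least squares of posterior ability means on the age basis (exact
because the residual variance is fixed). Starting values are
deterministic: alpha = 1, thresholds from inverse-logit marginal
cumulative frequencies, gamma = 0. Convergence: max parameter change
< 1e-4 or log-likelihood change < 1e-6, at most 500 cycles;
non-convergence flags the result rather than raising. Categories with no
observed responses are collapsed with a warning. The observed-data
log-likelihood trace is nondecreasing (a property test enforces this).

EAP scores are posterior means on the same grid; the CSEM is the posterior
SD (the "standard error of the EAP" in the IRT sense). Children with no
answered items receive their prior mean and SD. Scores stay on the latent
logit scale; no reporting rescale is applied by default.

## Reliability

Marginal reliability is the empirical statistic
r = Var(eap) / (Var(eap) + mean(csem^2)). Because ability rises roughly
4 SD across the age range, marginal reliability overstates precision for
same-age comparisons, so the package also computes the age-conditional
reliability r_i = 1 - csem_i^2 / Var(eap | age_i). The age-conditional
variance comes from a normal location-scale model — mean and log-SD linear
in age splines, fitted by ML (WLS for the mean given the scale, Fisher
scoring for the log-scale given the mean, iterated to a 1e-8 deliberate
log-likelihood tolerance). This is a lighter-weight stand-in for a GAMLSS
fit, which is used in this literature only to obtain Var(eap | age).

Two deliberate choices:

* The log-SD uses a leaner spline (single interior knot at 36 months)
  than the mean. At n = 5,000 a 7-df variance spline carries 6-12%
  boundary noise in the fitted SD, swamping the quantity of interest;
  3 df brings the worst-case error to a few percent. Penalized variance
  smoothers in GAMLSS serve the same purpose. The log-SD linear predictor
  is floored at log(1e-8) so degenerate (zero-residual) inputs return a
  finite fit.
* The per-month expected reliability curve smooths csem^2 on age with the
  same spline machinery and evaluates 1 - E[csem^2|age] / s(age)^2 at each
  month; months below the cutoff (default .80, the usual floor for
  population-level use) are flagged. Mean conditional reliability is
  reported both averaged over children and averaged over months, since
  either convention is defensible.

All reliabilities are invariant to affine rescaling of the score metric.

## DIF screening and the sensitivity analysis

DIF detection is a likelihood-ratio screen with anchor purification rather
than an alignment optimization (alignment's component-loss machinery is a
black box; the decision output — a flagged-item set and group comparisons
under partial invariance — is what downstream analyses consume):

1. Fit a multi-group GRM: item parameters equal across groups, group
   ability distributions free, reference group fixed to N(0, 1).
2. For each testable item, a likelihood-ratio test compares shared vs
   group-specific parameters for that item, holding all other ("anchor")
   item parameters and the group distributions fixed at the current fit
   and maximizing the marginal likelihood over the tested item's
   parameters directly (no inner EM); df = K_j x (G - 1).
3. Flag items at Benjamini-Hochberg FDR .05 (the screen tests every item,
   so a multiplicity correction is applied even though none is standard in
   this literature), re-fit with flagged items freed, and repeat until the
   flag set stabilizes (at most 3 rounds).

Holding anchors fixed is a two-stage approximation; with ~39 anchor items
and n = 1,000 per group its effect on the null distribution is negligible,
which the simulation-based acceptance test verifies directly (observed
null flag rates at or below the nominal FDR, p-values near-uniform;
>= 75% power for a 0.5-logit threshold shift).

The multi-group EM uses 71 quadrature nodes (spacing <= 0.2 over the span
of all group distributions +/- 6 SD) and SQUAREM-style extrapolation with
a monotone safeguard: two EM half-steps, a squared extrapolation, and a
fall-back to the plain EM step whenever the extrapolated likelihood is
lower. Inner M-step iterations are capped at 8 per cycle (generalized EM).

The sensitivity analysis estimates group-mean contrasts under full
invariance and under partial invariance (flagged items freed) and tests
the stacked contrast difference with a Wald chi-square, df = G - 1. The
covariance of the difference comes from a paired nonparametric bootstrap
over children (stratified by group so no resample loses a group; default
B = 200, smaller in the timed tests). Within the bootstrap, anchor item
parameters stay at the full-data fits and only group distributions and the
freed items' parameters are re-estimated — again a two-stage shortcut,
calibrated by simulation (null rejection ~5%). Zero flagged items is a
degenerate case returning chi-square 0, p = 1.

## Validity analyses

*Part correlations.* "Correlation after adjusting for age" is implemented
as both variables residualized on the age spline (the one-sided
semipartial is available by flag, and reports label the method, because
the field's terminology conflicts with its usual gloss). The SE uses
Fisher's z with degrees of freedom reduced by the adjustment dimension.
Reports attach the conventional convergent-validity verdicts (r >= .70
ideal, r >= .50 minimum).

*Multiple imputation.* Missing income and PHQ-2/GAD-2 items are imputed by
chained equations with predictive mean matching (k = 5 donors, 10 cycles,
m = 10 datasets, Bayesian coefficient draws), income on the log scale and
PHQ/GAD items rounded and clipped to 0-3. Predictors: the age spline,
education and race/ethnicity dummies, the other incomplete variables, and
the EAP score when supplied (which incomplete-data theory recommends when
the score is the analysis outcome). A guard rejects any variable more than
50% missing. Observed cells are never altered.

*Criterion regressions.* OLS of the EAP score on the age spline plus one
criterion block at a time — log income; education dummies (bachelor's
reference); race/ethnicity dummies (white non-Hispanic reference); the
PHQ/GAD total — pooled across imputations by Rubin's rules with
Barnard-Rubin degrees of freedom. The standardized effect size divides
each pooled coefficient by the age-conditional SD of the scores (residual
SD after the age spline); this definition is the package's own, stated
here because effect-size conventions for age-adjusted developmental scores
vary. Pairwise education contrasts use pooled linear contrasts with the
same df. Age adjustment is spline by default, linear by flag.

A caution on interpreting criterion regressions of EAP scores: the
posterior mean shrinks toward the age prior, so a regression of EAP
scores on a criterion estimates the latent effect times roughly the
score reliability given age (about 0.90 under the default synthetic
conditions: posterior-mean shrinkage of 1 - mean(csem^2), plus a small
latent-scale compression because criterion effects add residual variance
beyond the age prior while identification fixes it at 1). This
attenuation is intrinsic to EAP-based secondary analyses, not a defect of
imputation or pooling; the known-truth tests therefore validate the
criterion-analysis machinery on scores with no measurement error, and the
end-to-end (attenuated) estimates are reported alongside.

## Synthetic data generator

The generator is first-class, tested code; it defines the study conditions
under which every downstream stage is validated:

* Ages: uniform integer months 0-71 (observed yearly bands in this
  population are near-uniform). Default n = 5,001.
* Item bank: default 197 items; window midpoints spread over the age
  range, widths jittered log-normally and scaled by bisection so the
  exactly enumerated mean administered count matches the 39-item target.
  Domain composition interpolates from motor-heavy infancy (53% in year
  0) toward cognitive/language dominance by year 5; source-instrument
  labels follow the typical mix of pooled caregiver instruments.
  Categories: 2/3/4 with probability .6/.3/.1. Discriminations
  log-normal(log 2, 0.3); thresholds centered on the ability curve at the
  window midpoint (so item difficulty tracks the ages at which the item is
  administered) with random spread 0.5-0.9.
* Ability: theta = m(age) + criterion shifts + N(0, 1), with m a scaled
  logistic curve spanning 4 SD over 0-71 months (rapid early growth,
  flattening), centered to mean zero. Default criterion shifts (in
  residual-SD units): log income +0.09/unit, education no-HS -0.34,
  HS -0.27, some college -0.08, master's+ +0.05 (bachelor's reference),
  Black non-Hispanic -0.137, other non-Hispanic -0.113, Hispanic -0.237
  (white non-Hispanic reference), PHQ/GAD total -0.128 per unit.
* Covariates: education and race/ethnicity from the study's observed
  margins; income log-normal; PHQ/GAD items generated from a latent
  caregiver-distress variable through fixed cutpoints (so the four items
  correlate). Joint covariate dependence beyond this is not modelled —
  covariates are otherwise independent, which real data are not.
  Missingness is MCAR: income 7.2%; the four PHQ/GAD items jointly 10.8%
  (block missingness, mimicking planned missingness designs).
* Concurrent-instrument stand-ins: score columns constructed with chosen
  age-adjusted correlations to true ability (defaults follow the typical
  convergent/discriminant pattern of such studies, from .93 down to
  -0.20). These are synthetic stand-ins, not instrument scoring engines.
* DIF injection: per (item, group) threshold shifts and discrimination
  ratios, applied at response generation; recoverable by construction.
* All randomness flows from one root seed through named substreams (ages,
  bank, covariates, theta, responses, scores); identical configs give
  byte-identical datasets.

What passing tests on these data do *not* show: robustness to informative
(non-MCAR) missingness, to correlated covariates, to local item
dependence, to non-normal latent distributions, or to real instruments'
scoring idiosyncrasies — none of which the generator emulates.

## Problem sizes in the test suite

The acceptance-style tests run the study-scale conditions directly where
the check demands them (calibration recovery at n = 1,000 x 40 items;
criterion-effect recovery at n = 5,000 with the full 197-item bank and
default missingness; DIF calibration and power at n = 1,000 per group,
40 items, 20 replicates). Sensitivity-analysis replicates use n = 500-600
per group with 20 items and 30-60 bootstrap draws, sizes at which the
null calibration stabilizes while a full replicate set stays affordable;
`scripts/acceptance.py` reports DIF rates from 5 replicates per condition
for the same reason.

## Known limitations

* Unidimensional ability, logistic link, ML only — no multidimensional,
  nonparametric, or Bayesian variants.
* The DIF screen's anchored LRT and the bootstrap's fixed anchors are
  two-stage approximations; both are simulation-calibrated here but have
  no finite-sample guarantees under heavy contamination of the anchor set.
* Item-parameter standard errors are an optional block-diagonal
  observed-information approximation (other items held fixed).
* The ±5 SD extreme-score screen uses the score column's own mean/SD
  (an external reference can be supplied); it is applied per column over
  the whole sample.
* The imputation model is PMM-linear; strongly nonlinear
  covariate-outcome relations would call for a richer imputation model.
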