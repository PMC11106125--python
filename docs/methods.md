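# Methods

This note documents the statistical models implemented in `twinmod`, the
conventions and numerical choices behind them, what the synthetic-data
generator does and does not emulate, and the known limitations.

## The biometric model

For k phenotypes measured on both members of a twin pair, the ACE model
writes the within-person covariance as `a·aᵀ + c·cᵀ + e·eᵀ` with
lower-triangular path matrices (a Cholesky factorization per component).
Cross-twin covariance blocks weight the A term by the zygosity correlation
(1 for MZ, 0.5 for DZ), the C term by 1 and the E term by 0. These
component correlations are fixed constants of the design, not parameters.
Means are constrained equal across birth order and zygosity, and variances
equal across zygosity; both are consequences of how the likelihood is
parameterized rather than explicit constraints.

### Moderation

A moderated path is `p + β·M`, where M is the observed (mean-centered)
moderator value of the individual whose path it is; cross-twin A/C blocks
use `a(M₁)·a(M₂)ᵀ`. The moderator may itself be a dependent variable — its
own row of paths is then structurally unmoderated, and its realized value
enters the other rows. The joint density this induces is exactly the
definition-variable likelihood the models evaluate: conditional on the
moderator values, all remaining variables are linear in independent normal
latents, so the pair vector is normal with the per-pair covariance
`Σ(M₁, M₂)`.

Two model layers use this construction:

* **Phenotypic moderation** — a 2×2 per-individual Cholesky over
  (moderator-linked variable, outcome) with moderated paths, and free
  symmetric cross-twin latent correlation matrices per zygosity (estimated,
  not decomposed into A/C/E). Model 1 takes the first variable as its own
  moderator and frees the covariance and outcome-specific slopes; model 2
  uses an external moderator (its main effects regressed out upstream) and
  additionally frees the first variable's own slope.
* **Biometric moderation** — the full ACE Cholesky with A- and E-slopes
  freed on the moderated paths: the bivariate design (moderator = first
  variable) frees paths 21 and 22; the trivariate design (external-scale
  moderator modeled as the first dependent variable) frees paths 21, 22,
  31, 32, 33. C paths are dropped by default, following the empirical
  justification that their contribution is null; they can be retained with
  a flag. The trivariate fit reports only the moderator–outcome sub-results
  by default, with the full slope table behind a flag.

### Liability thresholds and identification

Binary traits are dichotomized standard-normal liabilities. Thresholds may
shift linearly with covariates (age, centered; sex, 0/1; optionally the
moderator, absorbing its main effect on a binary dependent variable).
Ordinal data carry no intrinsic scale, so the liability is identified by
rescaling the variable's unmoderated path row to unit total variance at the
moderator's centering point (M = 0); moderated variance then varies freely
with M. Technically the row's raw specific-E entry is fixed at 1 and the
whole row is rescaled inside the likelihood, which leaves no flat ridge in
the parameter space. Moderation slopes are not rescaled. Absolute moderated
path values are therefore anchored at the moderator mean; other anchoring
conventions would shift slope magnitudes slightly.

### The likelihood

Each pair contributes the likelihood of its observed entries
(full-information ML): a multivariate-normal density over observed
continuous entries times the probability of the observed category rectangle
under the conditional normal of the latent liabilities. Missing entries are
marginalized by dropping rows/columns; pairs missing the moderator are
excluded from moderation fits (definition variables cannot be missing).
Up to two ordinal entries per pair are supported (one liability variable on
both twins), so rectangle probabilities are univariate or bivariate normal.

Bivariate-normal CDF values come from Owen's T (`scipy.special.owens_t`),
deterministic and accurate to ~1e−14; rectangles lying in an upper tail are
reflected before inclusion–exclusion to avoid subtracting CDF values near
1. Covariance matrices that leave the positive-definite cone during
optimization yield −∞ log-likelihood (a rejected step). Pairs are grouped
by missingness pattern once per fit so each evaluation is batched linear
algebra; 2×2 blocks use closed forms.

## Estimation and inference

Optimization is quasi-Newton (L-BFGS-B) with numerical gradients,
convergence at projected-gradient norm < 1e−5. On failure, up to five
starts are tried, jittered 10% around the start values. Moderated liability
models can be *bimodal* in the outcome-specific E slope: the moderated path
`e + β·M` may cross zero inside the observed moderator range, creating a
shallow secondary basin near a smaller |β|. Moderation fits therefore
launch from a ladder of slope starts (−0.6, 0, +0.6 by default) and keep
the best deviance; single-start fits from a shallow basin attenuate the
slope, which simulation at 100k pairs confirms is an optimization artifact,
not an estimator bias.

Degrees of freedom follow the observed-statistics convention (number of
non-missing data entries minus free parameters) and AIC is deviance-based,
`AIC = −2LL − 2·df` — the convention that reproduces standard
twin-modeling software output. Likelihood-ratio tests use the central
chi-square; no boundary mixture correction is applied because variance
paths are squares of unconstrained reals and moderation slopes are
interior. Confidence intervals are 95% profile-likelihood bounds: the
parameter values where the profiled deviance rises 3.841 above its minimum,
found by outward stepping and bisection to 1e−4 with warm-started nuisance
re-optimization; a bound that fails to cross within ten curvature-based SDs
is reported open-ended. Correlation CIs are profiled on the atanh scale.
The drop-C decision rule and "CI contains 0" significance calls are left to
the caller; no multiple-testing correction is applied.

## Saturated twin correlations

The correlation stage estimates, by joint ML over the same pairwise
likelihood, a within-person correlation matrix constrained equal across
birth order and zygosity, plus symmetric cross-twin matrices per zygosity.
Variable scales dictate the correlation type (Pearson, polyserial,
polychoric) automatically. Correlations are parameterized as hyperbolic
tangents of unbounded parameters; a proposed joint pair matrix outside the
PSD cone is projected back by flooring its spectrum at 1e−8 and
renormalizing the diagonal. Same-sex and opposite-sex DZ pairs are pooled
into one DZ group (sex effects live in the residualization / threshold
model). A standalone polychoric estimator for two-way contingency tables
(multinomial likelihood over bivariate-normal rectangles) serves as a
small, independently testable building block.

## Preprocessing

Scale scoring supports mean, mean-times-k and sum rules with excluded items
and not-applicable codes, plus dichotomization of a skewed composite at
zero. Cronbach's alpha is the internal-consistency check. Continuous scores
are log-transformed and then residualized on centered age and sex by pooled
individual-level OLS; the log-then-residualize order is forced by the fact
that residuals can be negative. Ordinal variables are never residualized —
their covariates enter the threshold model. Missing continuous scores are
imputed by multivariate-normal EM at the score level (convergence when the
largest parameter change falls below 1e−6, capped at 500 iterations), after
excluding individuals missing more than 75% of the model variables; binary
liability variables are never imputed, and observed cells are untouched.

## The synthetic-data generator

The generator draws A/C/E latent factors with the twin-design cross-twin
correlations, builds phenotypes through the Cholesky rows (the moderator's
row first, its realized value feeding the moderated rows), dichotomizes
liabilities at covariate-shifted thresholds, and applies MCAR missingness.
Output is analysis-ready: scores on the adjusted (residual/liability)
scale with unit variances at the moderator mean.

The default study configuration emulates the motivating design: three
phenotypes with AE etiology (standardized variance shares 0.606/0.394,
0.40/0.60, 0.51/0.49 — the first pair renormalized after dropping a 0.05
shared-environment share), within-person correlations 0.15/0.23/0.27 split
between A and E in proportion to the component scales, orientation
prevalence 6.8% (threshold 1.491), ages normal(37.6, 2.94) truncated to
[18, 60] and shared within pair, sexes Bernoulli(0.5) (shared within MZ
pairs, independent within DZ pairs), no threshold sex shift, a single true
moderation slope of −0.38 on the orientation-specific E path with the
gender-nonconformity score as moderator, and 319 MZ + 553 DZ pairs.

What it does *not* emulate: item-level questionnaire responses, informative
missingness or ascertainment bias, sex-limitation (different architecture
by sex), age trends in the phenotypes, and non-normal measurement error.
Passing recovery tests therefore show the estimators work when the model's
assumptions hold at study scale; they cannot certify robustness to the ways
real questionnaire data violate those assumptions.

One structural note: under variance moderation the marginal association
between the moderator and the binary outcome is not the latent covariance —
with the default configuration the negative variance slope more than
offsets the positive mean effect, so the observed point-biserial
correlation is near zero even though the latent covariance is 0.27. This is
a property of the model, and the saturated (homoscedastic) correlation
stage applied to moderated data will reflect it.

## Validation problem sizes

The simulation suites run at sizes chosen to give informative Monte-Carlo
error on a single CPU: moment consistency of the generator against the
implied pair covariance at 10⁶ pairs (4 MC SEs); moderation-slope recovery
over 60 replicates of 1500 MZ + 1500 DZ pairs (mean within 3 MC SEs of
−0.38, sign correct in >95%); null LRT calibration over 150 replicates of
250+250 pairs (rejection at 3.84 within binomial error of 5%); profile-CI
coverage for a² over 120 replicates of 250+250 pairs (95% within binomial
error); and a quadrature oracle for the mixed likelihood on model-drawn
pairs (agreement to 1e−6). The CI bands in these checks are standard-error
bands at the stated replicate counts.

## Known limitations

* Only one ordinal variable (measured on both twins) per model; more would
  require >2-dimensional rectangle integration.
* No dominance (ADE) models, sex-limitation models, or rater/sibling
  extensions.
* Gradients are numerical; very large models (many free slopes) fit slowly.
* EM imputation assumes joint normality of the continuous scores and MCAR
  (or at least ignorable) missingness.
* The moderator is treated as measured without error; moderation of means
  beyond main-effect regression (growth models) is out of scope.
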