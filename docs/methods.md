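# Methods

## Scientific setting

Black-American (BA) patients with multiple sclerosis carry, on average, more
disability than White-American (WA) patients, measured by the Expanded
Disability Status Scale (EDSS).  One candidate pathway runs through chronic
active lesions: the share of a patient's FLAIR white-matter lesions that are
paramagnetic rim lesions (PRLs) is higher in BA patients, and PRL burden is
itself associated with disability.  This package implements the causal
mediation analysis that quantifies how much of the race–EDSS disparity is
transmitted through the PRL percentage, together with a synthetic-cohort
generator that reproduces the statistical structure of the 117 BA / 123 WA
study population, so that every stage of the pipeline can be exercised and
validated end to end without access to the original patient-level data.

## The mediation model

Three linear models are fitted by ordinary least squares, with race coded
0/1 (BA = 1), DMT (disease-modifying therapy) as two dummies (lower
efficacy, untreated) against a higher-efficacy reference, and zip-code
income rescaled to $10,000 units:

* total-effect model: `EDSS ~ race + age + sex + duration + DMT +
  non-PRL volume + income`;
* mediator model: `PRL% ~ race + age + DMT` (race coefficient alpha);
* outcome model: `EDSS ~ race + PRL% + age + DMT + non-PRL volume`
  (race coefficient = average direct effect ADE; PRL% coefficient beta).

With linear models and no treatment–mediator interaction, the average
causal mediation effect is the product of coefficients, `ACME =
alpha * beta`; this coincides with the potential-outcomes (simulation-based)
ACME definition in the linear no-interaction case, which is why the package
uses the analytic product rather than simulated counterfactuals.  The total
effect inside the mediation engine is defined as `ACME + ADE`, so the
decomposition is exact by construction; the richer Methods-style
total-effect model is fitted and reported separately and is *not* forced to
agree (its race coefficient also absorbs group differences in non-PRL
volume and the other covariates).  Proportion mediated is
`ACME / (ACME + ADE)`.

EDSS is an ordinal half-step scale but is modelled as continuous throughout,
deliberately mirroring the study design; no ordinal model, mixed effects or
robust standard errors are offered.

## Bootstrap inference

Nonparametric bootstrap: patients are resampled iid with replacement (whole
cohort by default; a stratified-by-race flag exists), both models are
refitted per replicate, and all four quantities are recomputed.  Default
25,000 replicates.  Confidence intervals use the percentile method with
linear interpolation of order statistics (numpy's `method="linear"`
convention, fixed and documented).  P-values use the sign-flip rule
`p = 2 min(frac <= 0, frac >= 0)`, capped at 1; when no replicate crosses
zero the result is reported as `< 2/n_boot`.  This convention is a package
choice; the study's mediation p-values come from an unstated convention and
no equivalence is claimed.

Replicates whose resampled design is rank deficient (a dummy column can
vanish from a resample) are redrawn from the continuing index stream,
counted, and capped at 1% of `n_boot`; beyond the cap the cohort is declared
too degenerate to bootstrap.  Replicates with `|total effect| < 1e-6` are
excluded from the proportion-mediated distribution only, and counted.  The
implementation solves the weighted normal equations for all replicates in
batched linear algebra; a unit test pins it to a naive per-replicate refit
fed the identical resample index stream.

The per-replicate proportion mediated is a ratio whose denominator can
approach zero, so its bootstrap distribution is heavy-tailed; its interval
can fail to bracket the point estimate when unstable replicates were
excluded (flagged via `n_unstable`).  For the same reason, *averaging*
per-cohort proportion ratios across many simulated cohorts is undefined
(the sampling distribution of the total effect crosses zero at n = 240);
wherever this package aggregates the proportion across simulations it
reports the ratio of averaged effects instead.

## Sensitivity analysis

Sequential ignorability — mediator as-if random given treatment and
covariates — is probed by re-identifying the ACME as a function of rho, the
correlation an unobserved confounder would induce between the mediator-model
and outcome-model disturbances.  In the linear structural-equation case:

    ACME(rho) = alpha * (s1/s2) * [rho~ - rho * sqrt((1 - rho~^2)/(1 - rho^2))]

where s1, s2 are the residual standard deviations of the reduced
total-effect model (outcome on treatment + covariates, mediator excluded)
and of the mediator model, and rho~ is the sample correlation of those two
residual vectors.  Both models are fitted on the outcome model's
non-mediator covariate set; sharing the covariate set is what makes the two
anchor identities exact, and the package verifies them numerically rather
than trusting the formula's provenance: `ACME(0)` equals the
product-of-coefficients ACME to machine precision (Frisch–Waugh–Lovell),
and `ACME(rho~) = 0`.  The curve is strictly decreasing in rho when
`alpha > 0`; the zero crossing is located by bisection on the closed form
over (-0.999, 0.999) to 1e-6, and therefore does not depend on the grid
(default: -0.9 to 0.9 in steps of 0.01).

## Synthetic-cohort generator

The generator is the package's study stand-in; all cohorts it emits are
synthetic.  Per race it draws age, disease duration and income from
truncated normals (lower bounds 18 y, 0 y, $1,000), sex and DMT from
categorical distributions, non-PRL FLAIR volume from a lognormal
moment-matched to the published group mean/SD, and the FLAIR lesion count
from a zero-truncated negative binomial (every patient has at least one
lesion, so the PRL percentage is always defined; truncation raises the
realized mean count ~2% above the matched moment).  Defaults reproduce the
published group summaries for 117 BA / 123 WA patients.

Two mediator modes:

* **linear** — `M = 5.3102 + 4.65*BA - 0.05*age + 0.5*lower +
  0.5*untreated + eps`, residual SD 15.25 (BA) / 7.50 (WA).  M is an
  unbounded Gaussian, so OLS recovers the structural coefficients without
  truncation bias; it can stray outside [0, 100] (documented).  The age and
  DMT loadings are not published; small values were chosen once so the
  covariates are non-degenerate, and the intercept then set so the WA group
  mean PRL% is 3.40.
* **count** — per-patient rim probability `logistic(-3.684 + 0.647*BA +
  tau_r * Z)` with per-race overdispersion SD tau (1.262 BA / 0.862 WA),
  PRL count binomial given the FLAIR count, mediator = realized percentage,
  always in [0, 100].  A single shared tau cannot reach all four published
  targets (it misses the WA prevalence by ~2.4 points), so tau is
  race-specific, mirroring the per-race residual SDs used elsewhere.  The
  logit-normal overdispersion family is a package choice.  `calibrate_count_model`
  solves (intercept, tau) per race against the published mean percentage
  and prevalence by Gauss–Hermite quadrature plus the zero-truncated
  negative-binomial generating function — deterministic, no simulation —
  and the race effect is the intercept difference.

The outcome equation is shared by both modes:
`EDSS = -0.8627 + 0.60*BA + 0.021*M + 0.05*age - 0.58*lower -
0.31*untreated + 5e-5 * non-PRL volume + eps`, residual SD 1.9 (BA) /
1.5 (WA), chosen so the marginal EDSS SDs match the published 2.11/1.62
after the covariate contributions.  The published non-PRL volume
coefficient prints as 0.00 (sub-rounding); the small positive default keeps
the covariate non-degenerate.  The intercept is set so the WA mean EDSS is
1.3; the BA mean then follows from the structural equation (~2.31 against
the published 2.34).  EDSS is generated latent-continuous; an optional flag
rounds to the clinical 0–9.5 half-step grid, but recovery checks use the
latent value to avoid rounding bias.  Residual SDs are race-specific while
the OLS stages assume homoscedasticity — deliberate, mirroring the study's
own mismatch.

An optional latent standard-normal confounder U enters both the mediator
and the outcome disturbance with a common loading (`confounder_strength`,
default 0).  At 0 the two disturbances are independent by construction; a
positive loading biases the naive ACME upward and raises the residual
correlation rho~, which is how the sensitivity tests place rho~ near 0.15.
In count mode the confounder perturbs the rim-probability deviate through
the same scaled path, so the channel exists in both modes.

What the generator does **not** emulate: spatial lesion structure,
longitudinal trajectories, missing data, scanner effects, zero-inflation of
the PRL percentage beyond what prevalence implies, and any
covariate–covariate dependence other than race (age, DMT, volume are drawn
independently within race).  Passing tests therefore demonstrate that the
pipeline recovers the structure this generator encodes, not that the
published estimates are correct for the real cohort.

## Group-comparison layer

Welch's t (default; pooled-variance as a flag) for mean(SD) rows, Wilcoxon
rank-sum with midranks for median[IQR] rows — exact enumeration of all rank
assignments up to combined n = 12, tie-corrected normal approximation with
continuity correction beyond — Yates-corrected chi-squared for 2x2
proportions, Fisher's exact test for small expected counts (< 5
convention), and plain Pearson chi-squared for the 3-level DMT table (the
continuity correction is a 1-df device).  Degenerate tables with a zero
margin return p = 1 under Fisher by convention and are an error under
chi-squared.  Tests are assigned per variable by an explicit plan, not by
automated normality testing; all tests are two-sided; no multiplicity
adjustment.  The Yates p-value tracks Fisher's within 0.02 in the
significance region (p <= 0.05) but can differ by ~0.1 near p = 1, where
the two-sided exact p-value is strongly discrete.

## Numerical and aggregation choices

* OLS via pivoted QR; rank deficiency is an error naming the dependent
  columns; standard errors from `sigma^2 (X'X)^{-1}` with
  `sigma^2 = RSS/(n - rank)`; p-values from the t distribution.
* Simulation sizes: headline recovery uses 200 cohorts at the study's own
  n = 117/123; count-model and EDSS calibration checks use 50,000 patients
  per group (Monte-Carlo SE ~0.07 points on the mean percentage, ~0.2
  points on prevalence); coefficient-recovery property tests use up to
  100,000 per group; bootstrap coverage is assessed over 300 cohorts at
  1,000 replicates.
* Seeds: every stochastic routine takes an explicit integer seed into
  `numpy.random.default_rng`; identical (config, seed) reproduces cohorts
  and bootstrap distributions bit-for-bit.

## Known limitations

* The mediator model treats a bounded percentage linearly; linear mode
  makes this internally consistent, count mode exposes the approximation.
* The proportion-mediated bootstrap interval inherits ratio instability.
* The sensitivity analysis covers the ACME only (no ADE sensitivity, no
  R-squared parameterization).
* Single mediator, single time point, no interaction terms; none of the
  quasi-Bayesian inference variants are implemented.
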