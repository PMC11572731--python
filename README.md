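# prl-mediation

Causal mediation analysis of paramagnetic rim lesions (PRLs) and
race-related disability in multiple sclerosis.

Black-American (BA) patients with MS experience greater disability —
measured by the Expanded Disability Status Scale (EDSS) — than
White-American (WA) patients.  PRLs, a subset of chronic active lesions
detectable on susceptibility-based MRI, are both more frequent in BA
patients and associated with disability.  This package implements the full
statistical pipeline that quantifies how much of the race–EDSS disparity is
mediated by the percentage of FLAIR lesions that are PRLs:

* **synthetic cohort generator** — patient-level cohorts (default 117 BA /
  123 WA) with the covariate distributions and structural coefficients of
  the study population, in a linear-Gaussian mode for exact coefficient
  recovery and a lesion-count mode for a realistic bounded mediator, plus a
  deterministic calibrator of the count model to target mean PRL
  percentages and prevalences;
* **group comparisons** — the characteristics-table layer (Welch/pooled t,
  Wilcoxon rank-sum with exact small-sample enumeration, Yates-corrected
  chi-squared, Fisher's exact test);
* **three linear models** — total-effect, mediator and outcome OLS fits
  with declarative specifications;
* **mediation engine** — product-of-coefficients estimation of the average
  causal mediation effect (ACME), average direct effect (ADE), total effect
  and proportion mediated, with nonparametric percentile-bootstrap
  confidence intervals (default 25,000 replicates) and sign-flip p-values;
* **sensitivity analysis** — ACME as a function of the mediator–outcome
  residual correlation rho under the sequential-ignorability assumption,
  with the zero-crossing diagnostic.

## The model

With race `T` (BA = 1), mediator `M` (PRL percentage), outcome `Y` (EDSS)
and covariates `X` (age, DMT category, non-PRL lesion volume, ...):

    M = a0 + alpha*T + f(X) + e1          (mediator model)
    Y = c0 + gamma*T + beta*M + g(X) + e2 (outcome model)

    ACME = alpha * beta        ADE = gamma
    total effect = ACME + ADE  proportion mediated = ACME / (ACME + ADE)

The sensitivity analysis re-identifies the ACME when an unobserved
confounder induces correlation `rho` between `e1` and `e2`; it equals the
product-of-coefficients ACME at `rho = 0` and vanishes at the observed
residual correlation `rho~`.  See `docs/methods.md` for the closed form,
the bootstrap conventions, and the generator's calibration.

## Worked example

```python
from prl_mediation import (GeneratorConfig, generate_cohort, fit_named_model,
                           point_estimates, bootstrap_mediation,
                           sensitivity_from_cohort)

cohort = generate_cohort(GeneratorConfig(seed=3))   # 117 BA / 123 WA patients
med = fit_named_model(cohort, "mediator")
out = fit_named_model(cohort, "outcome")
pe = point_estimates(med, out)
res = bootstrap_mediation(cohort, n_boot=25000, seed=3)
sens = sensitivity_from_cohort(cohort)
```

prints (via the fields shown):

```
alpha = 5.911 (SE 1.557), beta = 0.0267
ACME = 0.1579, 95% CI [0.0156, 0.3419], p 0.02752
ADE  = 1.0862, 95% CI [0.5973, 1.5772], p < 8e-05
total effect = 1.2441, proportion mediated = 0.127
rho~ = 0.180; ACME zero crossing = 0.180
```

Reading: in this simulated cohort BA race raises the PRL percentage by 5.9
points (`alpha`), each PRL-percentage point adds 0.027 EDSS points
(`beta`), so 0.16 EDSS points of the 1.24-point race effect — about 13% —
flow through PRLs; the bootstrap excludes zero for both effects.  An
unobserved confounder would have to induce a residual correlation of 0.18
to explain the mediation effect away entirely.  Single cohorts at n = 240
are noisy; averaged over 200 generator seeds the point estimates recover
the generating values (ACME 0.098, ADE 0.60, alpha 4.65).

The same pipeline is scriptable from the shell:

```sh
prlmed simulate --seed 1 --out cohort.csv
prlmed mediate  --seed 1 --cohort cohort.csv --out mediation.json
prlmed report   --seed 1 --out-dir run1/      # table one + models + mediation
                                              # + sensitivity, markdown & JSON
```

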