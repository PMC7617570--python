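# Methods

## Model family

The package fits mixed-effects location scale (MELS) regressions to a
clustered continuous outcome. Units (students) are nested in clusters
(schools); writing *y<sub>ij</sub>* for the outcome of unit *i* in
cluster *j*:

- **Mean (location) function** — linear in covariates with a cluster
  random intercept *u*<sub>0*j*</sub> and optionally a cluster random
  slope *u*<sub>1*j*</sub> on the prior score *x*<sub>1</sub>.
- **Log variance (scale) function** — the residual variance satisfies
  ln σ²<sub>e,ij</sub> = α'w<sub>ij</sub> + *v*<sub>*j*</sub>, where the
  covariate set may be empty (intercept only) and the cluster scale
  effect *v*<sub>*j*</sub> is optional. The log link guarantees a
  positive variance for every unit.
- **Random effects** — the per-cluster vector (u0[, u1][, v]) is
  multivariate normal with unstructured covariance Σ, independent of the
  covariates and residuals. Covariances are stored as a full matrix;
  correlations are derived at reporting time.
- **Residuals** — conditionally normal: e<sub>ij</sub> ~ N(0,
  σ²<sub>e,ij</sub>).

Eight named variants span the useful lattice: (1) random intercept,
(2) + random scale, (3) + prior score in the variance function,
(4) random slope, (5) random slope + scale, (6) slope + full variance
function, (7) student sociodemographics in both functions,
(8) + school characteristics in both functions. Each model nests its
parent: setting the extra parameters to zero reproduces the parent's
likelihood exactly, and the test suite asserts this across the lattice.

Key assumptions worth keeping in mind: cluster-level exogeneity (random
effects independent of covariates), conditional normality of residuals
(no floor/ceiling censoring), and log-normality of the cluster-specific
variances. Estimates are descriptive cluster differences, not causal
effects.

## Priors

- Regression coefficients (β, α): independent N(0, 10⁶) — effectively
  flat at the scale of standardized scores. Configurable via
  `PriorSpec.coef_variance`.
- Random-effect covariance Σ: inverse-Wishart IW(d + 1, 0.1·I) by
  default, a minimally informative choice; the implied marginal on each
  variance in the d = 2 case is invgamma(1, 0.05) (mode 0.025, no
  finite mean). With
  hundreds of clusters the likelihood dominates; with few clusters
  (J ≲ 30) variance estimates are pulled toward ~0.01–0.05, which
  matters when the true variance is near zero (total-shrinkage behavior
  is therefore demonstrated in the tests with a tighter scale, 0.01·I).
  Both hyperparameters are configurable; a sensitivity sweep is a
  one-line loop over `PriorSpec(iw_scale=...)`.

## Sampler

A Metropolis-Hastings-within-Gibbs scheme on the complete-data
posterior, fully vectorised across clusters:

1. **Mean-function effects (u0[, u1])** — exact conjugate multivariate
   normal draws given the scale effects, using the conditional prior
   N(Σ<sub>uv</sub>σ<sub>v</sub>⁻²v<sub>j</sub>, Σ<sub>u|v</sub>) and
   per-cluster weighted sufficient statistics (closed-form 1×1/2×2
   solves, all clusters at once).
2. **Scale effects v<sub>j</sub>** — per-cluster random-walk MH. The
   conditional log target is −½(n<sub>j</sub>v + A<sub>j</sub>e⁻ᵛ) plus
   the conditional normal prior, with A<sub>j</sub> the weighted
   residual sum of squares; step sizes are tuned per cluster by
   Robbins–Monro toward 0.44 acceptance during burnin only.
3. **Translation ("recentring") moves** — exact Gibbs draws of a shift δ
   along the directions (β0 + δ, u0 − δ), (β1 + δ, u1 − δ) and
   (α0 + δ, v − δ). The likelihood is invariant along these directions,
   so δ has a closed-form normal conditional from the priors alone.
   These implement the hierarchical-centering idea as valid directional
   Gibbs steps and remove the random-walk behavior of the intercepts
   against the mean of the random effects.
4. **β** — conjugate weighted Bayesian regression draw.
5. **α** — block random-walk MH with proposal covariance matched to the
   curvature of a log-variance regression (½X'X)⁻¹, global scale tuned
   toward 0.23 (0.44 when scalar) during burnin.
6. **Σ** — conjugate inverse-Wishart draw IW(df₀ + J, S₀ + U'U).

Adaptation is frozen at the end of burnin, preserving detailed balance
during monitoring. Initial values are overdispersed perturbations of
crude moment estimates (OLS for β, within-cluster log variances for α
and Σ). All randomness flows from one `SeedSequence`, so a fixed seed
gives bit-identical chains; the sampler state depends on the data only
through permutation-invariant sufficient statistics.

Defaults mirror common practice for these models — 4 chains,
5,000 burnin + 10,000 monitoring iterations, no thinning — but every
run in the test and acceptance suites states its own (smaller) sizes.

## Diagnostics and model comparison

- **R̂ and ESS** are the rank-normalised split-R̂ and bulk effective
  sample size, delegated to arviz. Default gates (used by the CLI):
  R̂ < 1.05 and ESS > 400.
- **DIC** is computed *conditionally on the cluster effects*:
  D̄ + p<sub>D</sub> with p<sub>D</sub> = D̄ − D(posterior means), the
  deviance being −2 log p(y | params, effects). The conditional focus
  matches the cluster-level questions the model is asked (the marginal
  focus would integrate the effects out); the choice is stated here
  because the two can rank models differently in edge cases.

## Derived quantities

All reported at a common reference covariate profile (`ReferenceProfile`;
defaults: sample means of the variance-function covariates, the sample
mean of x1 for mean effects, and the mean per-cluster variance of x1 for
the slope component):

- shrunken cluster mean effects u0<sub>j</sub> + u1<sub>j</sub>·x̄ and
  scale effects, posterior means with equal-tailed 95% credible
  intervals (interval type stated in output metadata);
- cluster variances σ²<sub>e,j</sub> = exp(α'x̄ + v<sub>j</sub>);
- the decomposition u1<sub>j</sub>²·Var(x1) + σ²<sub>e,j</sub> with the
  slope component's share;
- plausible value ranges center ± z·√variance (optionally
  exponentiated — the two operations commute), the population-averaged
  variance exp(α0 + σ²ᵥ/2) (log-normal mean), within-cluster 95%
  achievement ranges 2z·√σ², percent variance explained and the VPC for
  a standardized outcome;
- ranks (ties broken by table order) and flags. A cluster is flagged
  when its credible interval excludes the population-average comparator:
  0 for mean effects; for variance effects the log-normal mean
  exp(α'x̄ + σ²ᵥ/2) is used as the primary comparator (coherent with the
  population-averaged variance above), while exp(α'x̄) is also reported
  by the CLI since either convention appears in practice.

## Synthetic data generator

The generator emulates the structure of a large urban school system:

- **School sizes**: discretized log-normal with mean 153 and log-SD 0.4,
  truncated to [14, 330]. Only the mean and range of the emulated system
  are known; the log-SD is a package choice, and truncation shifts the
  realised mean by ≲2%.
- **Prior score x1**: between-school mean component with variance equal
  to the configured intraclass correlation (default 0.2) plus a
  within-school component, marginal variance ~1. Grammar
  (selective-admissions) schools get a +1.5 SD intake shift — the
  selection effect is known only qualitatively, so both numbers are
  stated defaults, not estimates.
- **Covariates**: binary student covariates drawn independently within
  school at fixed prevalences (74%/26% summer born, 50% girls, 61%
  ethnic-minority across five dummy groups, 40% English as a second
  language, 14% SEN, 35% FSM); school categoricals (type, admissions,
  gender, religious) at the emulated system's proportions.
- **Outcomes**: cluster effects from N(0, Σ), then y from the model.
  With the bundled Model 1/2 reference estimates as truth, the implied
  y–x1 correlation is ≈ 0.72 and the residualized outcome variance obeys
  the law of total variance σ²ᵤ + exp(α0 + σ²ᵥ/2) (both asserted in
  tests at the ~71,000-student scale).

What the generator does **not** emulate: floor/ceiling effects in the
outcome, dependence between student covariates and x1 (optional in
principle, independent by default), within-school sociodemographic
segregation beyond the grammar intake shift, and any real geography.
Passing recovery tests therefore demonstrate correctness of the
estimation machinery under the model's own assumptions, not robustness
to the ways real administrative data violate them.

The bundled `REFERENCE_ESTIMATES` (Models 1–8) are posterior-mean
parameter values from a large London secondary-school application
(71,321 students in 465 schools, standardized age-11/age-16 scores);
they serve as realistic generating truths and as the inputs to the
derived-quantity arithmetic in `scripts/acceptance.py`.

## Numerical choices

- Log-variance linear predictors are clipped to ±40 before
  exponentiation; a non-finite deviance aborts the chain with a
  diagnostic rather than continuing silently.
- Near-singular Σ draws are jittered by 1e-10·I with a warning.
- The quadrature oracle (`marginal_loglik_quadrature`) supports
  random-intercept specs (d ≤ 2 integral per cluster): per-cluster
  damped-Newton mode search with analytic gradient/Hessian, then
  Gauss–Hermite nodes centred and scaled at the mode (25 nodes per
  dimension by default; stable to <1e-6 relative change between 25 and
  35 nodes on the test problems). It is a validation oracle for the
  sampler, not an estimation route.
- Standardization is computed on the supplied analysis sample and is
  idempotent; the affine constants are retained for raw-scale recovery.
  Whether standardization precedes or follows any sample restriction is
  the caller's choice; the package standardizes whatever sample it is
  given.
- Missing values: complete-case, with a logged drop count.

## Problem sizes used in the checks

The test suite and acceptance script run at desk scale, chosen to keep
the statistical properties detectable rather than to reproduce any
specific application: the main recovery check uses 200 schools of 100
students with 2 chains × (1,000 + 2,000) iterations; model-comparison
and flagging properties use 20–60 schools with short chains over 3–20
replicates; oracle comparisons use 3–4 small clusters where brute-force
integration is exact. At these sizes the recovered σ²ᵥ has posterior SD
≈ 0.006, so individual data realisations move the estimate by about
±0.01 around the generating value 0.037.

## Known limitations

- No Tobit/censored extension for floor–ceiling effects, no t or skew
  residuals, no random slopes inside the variance function, no
  three-level nesting, no multivariate outcomes.
- DIC is conditional-focus only; no marginal likelihood or Bayes
  factors.
- The quadrature oracle does not support random-slope specs (d = 3
  integrals); sampler validation for Models 4–6 rests on parameter
  recovery and nesting checks instead.
- Small-J variance estimates are prior-sensitive (see Priors above).
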