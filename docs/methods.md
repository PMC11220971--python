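# Methods

## Model

`crtraj` fits finite mixtures of linear mixed models (latent class mixed
models) to long-format cognitive data. Class membership is an
intercept-only multinomial logit with the last class as reference
(ξ_G = 0); covariates are deliberately kept out of the membership submodel
so that subgroup separation is carried entirely by the trajectory
structure. Conditional on class, the link-transformed outcome follows a
linear mixed model with

* class-common fixed effects β for baseline age, sex, neocortical amyloid,
  entorhinal tau and adjusted hippocampal volume (the default covariate
  set; any baseline columns can be configured),
* class-specific intercept and time slope δ_g,
* subject random intercept and slope with unstructured 2×2 covariance B
  shared across classes (an optional per-class proportional scaling ω_g is
  implemented but off by default),
* i.i.d. Gaussian residuals.

Because the model is linear-Gaussian given class, the random effects are
integrated analytically: each subject contributes
log Σ_g π_g φ(h(y_i); X_iβ + U_iδ_g, Z_iBZ_i' + σ²I) + Σ_j log h′(y_ij).
No numerical integration is used in the estimation path; Gauss–Hermite
quadrature appears only as an independent oracle in the tests.

### Link functions

Four monotone families normalize the outcome to the latent-process scale:

* **linear** — h(y) = (y − η₀)/η₁, fixed to the identity during
  estimation; intercepts and σ are then free.
* **equidistant / quantile splines** — an intercept plus a nonnegative
  combination of quadratic I-splines (integrated M-splines). "5 knots"
  counts boundary knots: 2 boundary knots at the observed outcome range
  plus 3 interior knots, giving K+1 = 6 basis functions and K+2 = 7 link
  parameters. Coefficients are parametrized as squares, which enforces
  monotonicity by construction; the basis is built once per fit from the
  observed outcomes, so a likelihood evaluation is a matrix–vector product.
* **beta** — the outcome is min-max rescaled into (ε, 1−ε) with ε = 1e-4
  and pushed through a Beta CDF with two positive shape parameters, then
  affinely relocated (4 parameters).

Identifiability: when the link is estimated, σ is fixed at 1 and the first
class' latent intercept at 0, the link carrying location and scale. This
is the standard latent-process convention; the exact convention of other
implementations may differ, which affects parameter values but not the
likelihood, classification, or fit indices.

### Estimation

The negative log-likelihood is minimized by BFGS over an unconstrained
parametrization (Cholesky factor of B, log σ, squared spline weights).
Continuous covariates are z-scored internally for conditioning; the
scaling is recorded on the fitted model and inverted by
`FittedModel.fixed_effects()`. Convergence requires three criteria
simultaneously — max |Δθ| < 1e-4, |Δℓ| < 1e-4 and g'H⁻¹g/npar < 1e-4
(up to 500 iterations) — and a non-converged fit is returned flagged
rather than raised, so the selection layer can filter it.

Multi-class fits use a short-run grid search: one-class estimates per link
family provide the backbone; departures perturb the class-specific
coefficients with Gaussian jitter scaled to half the marginal latent SD;
each departure runs a burn-in number of iterations (default 30, 15
departures) and the best interim solution is polished to full convergence.
The first departure is structured rather than random: per-subject OLS
(intercept, slope) features are clustered with k-means and the cluster
centers seed the class coefficients. This markedly improves the rate at
which few-departure searches find the dominant optimum while leaving the
random-restart behavior of the remaining departures untouched.

### Selection

Admissible candidates must have converged with every modal class holding
at least 5% of the sample. Ranking is by SABIC
(−2ℓ + k·ln((N+2)/24)); relative entropy ≤ 0.5 is a hard gate. The
third published-style criterion — theoretical plausibility of the
trajectories — is not automatable; the report therefore retains the full
ranking and flags for human review instead of encoding it. Replication
stability ("most frequent model" over 10 seeded repeats) groups solutions
by modal-partition identity up to label permutation, operationalized as
adjusted Rand index = 1; frequency ties break toward the higher
log-likelihood, noted in the report.

Three-class solutions are labeled by rule: the class with the most
negative slope — by more than a configurable margin (default 0.05 latent
units/year) over the runner-up — is *Declining* (slope is keyed before
intercept, so a declining class may have the lowest baseline); of the
remainder, the higher intercept is *Resilient* and the lower *Normal*.
Ties fall back to generic labels with a warning rather than silent
guessing.

## Preprocessing conventions

* Hippocampal volume is adjusted by the regression method,
  adj = raw − b·(eTIV − mean eTIV), with b estimated by OLS within the
  cohort being processed; reference b/mean can be injected to replicate an
  external convention. By construction the adjusted volume is empirically
  uncorrelated with eTIV in the estimation cohort.
* The cognitive composite is the mean of five z-scores against cohort
  baseline reference statistics; lower-is-better components are
  sign-flipped; by default all five components must be present (the
  minimum is configurable and relaxations are logged).
* Inclusion: analysis baseline is the earliest cognitive visit within 365
  days (inclusive) of the first tau scan; retrospective visits before that
  baseline are dropped; subjects need ≥ 2 retained visits and complete
  covariates. Exclusion reasons are logged per subject. Time is measured
  in years (days/365.25) from each subject's baseline; sex is coded
  1 = female.
* The cognitive-reserve residual standardizes OLS residuals (observed −
  predicted baseline cognition) by the residual SD on n − p − 1 degrees of
  freedom — "standardized", not internally studentized.
* Positivity thresholds are strict inequalities as published: amyloid
  > 1.185 DVR, hippocampal atrophy < 6,723 mm³; boundary values are
  negative for both.
* Clinical progression: event at the first of two consecutive nonzero
  global CDR visits (timed at the first of the pair) or at a final nonzero
  visit; otherwise censoring at the last CDR assessment.

## Statistical comparisons

Dunn post hoc z-tests use tie-corrected pooled rank variance and two-sided
p-values; the Hochberg correction is applied within each variable's
pairwise family (3 comparisons for 3 classes). Categorical variables use
Pearson χ² unless any expected cell count is below 5, in which case 2×2
tables get Fisher's exact test and larger tables a seeded Monte-Carlo
permutation p-value. Regional tau analysis regresses each ROI's SUVR on a
Resilient-vs-rest indicator (one estimate per ROI; a factor-coded
alternative sits behind a flag, since a single published estimate per ROI
leaves the coding ambiguous) with Benjamini–Hochberg adjustment across the
ROI family. The confirmatory intercept/slope contrast model is an
ordinary linear mixed model fitted with statsmodels `MixedLM` (dummy-coded
subgroups and subgroup×time interactions, Wald z-tests), since that step
needs standard errors, which the mixture fitter intentionally does not
provide.

## Synthetic cohorts

The default generator emulates the cohort the analysis targets: N = 200,
mixing 0.71/0.225/0.065; visit counts truncated-Poisson (floor 2, cap 10,
mean 6) with ~1.05-year spacing and jitter, follow-up capped at 10 years;
age ~ N(71.89, 9.41²), 59% women, amyloid ~ N(1.17, 0.19²) truncated above
0.9, entorhinal tau ~ N(1.33, 0.28²) truncated above 1, raw hippocampal
volume regressed on eTIV with slope 0.003 so head-size adjustment is
non-trivial; class intercepts 0.0/0.70/0.93 and slopes −0.02/0.00/−0.35
on the composite z-scale; covariates independent of class by default (a
confounded mode exists for stress-testing). A mild cubic-monotone warp
(y + 0.15·y³, inverted by Cardano's formula when generating) distorts the
observed scale so spline links have something to estimate; severity 0
disables it. Cognitive-reserve factors are drawn class-conditionally with
published-style means (e.g. verbal IQ 120.8/126.1/124.0; past activity
2.97/2.83/2.44) at the item level, and progression times are exponential
with class-specific hazards re-encoded as CDR visit sequences.

Under the default marginals the two stable classes genuinely overlap
(intercept gap 0.7 vs. random-intercept SD 0.35): the maximum-likelihood
solution itself blends them at moderate N, which is a property of the
data-generating design, not an optimizer failure. Recovery and
class-enumeration experiments therefore use the `well_separated` preset
(mixing 0.70/0.22/0.08, intercepts 0.0/1.5/1.2, slopes −0.01/0.00/−0.40,
no distortion), which represents the separability those experiments
presuppose. What passing recovery tests shows is that estimation and
selection work when distinct classes exist; it does not certify that any
particular real cohort contains separable classes.

## Problem sizes and numerical choices

Test and acceptance runs use scaled-down designs chosen as the package's
own defaults for desk-scale verification: recovery at N = 300 with 3
departures; class enumeration over 20 replicates at N = 250 with 2
departures and burn-in 20; pipeline determinism at N = 80 with a
linear-link, 2–3-class grid. Quadrature oracles use 55 Hermite nodes per
random-effect dimension. Modal assignment breaks posterior ties toward
the lower class index; candidate enumeration is a deterministic Cartesian
product; and every stochastic step (departures, replicate seeds,
Monte-Carlo p-values) derives from explicit integer seeds, which is what
makes the output bundle byte-reproducible.

## Known limitations

* No standard errors for mixture parameters (point estimation and
  classification suffice for the pipeline; Wald inference is delegated to
  the single-class confirmatory model).
* Ordinal/binary measurement models, multivariate latent processes and
  joint survival–longitudinal models are out of scope.
* The beta link can be poorly conditioned when optimal shape parameters
  are extreme; the spline families are the robust choice for strongly
  non-Gaussian outcomes.
* The exact fixed/random/link parametrization of other LCMM software is
  not reproduced parameter-for-parameter; agreement is at the level of the
  model class, fit indices and classification.
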