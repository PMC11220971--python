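# crtraj — latent-class trajectories of cognitive resilience

`crtraj` identifies data-driven subgroups of longitudinal cognitive change in
aging cohorts, after conditioning on demographics and imaging biomarkers of
Alzheimer's-disease pathology. Its target use case: cohorts of cognitively
unimpaired older adults with repeated cognitive-composite assessments
(e.g. PACC-5), a baseline amyloid-PET measure, entorhinal tau-PET, and
structural MRI. Because trajectory differences that survive adjustment for
age, sex, amyloid, tau and neurodegeneration are plausibly driven by a
latent factor, the higher-and-stable subgroup is interpreted as cognitively
*resilient*.

## The model

Subject *i* belongs to latent class *g* (probability
π_g = softmax(ξ)_g). Conditional on class, the link-transformed outcome
follows a linear mixed model:

    h(y_ij; η) = x_i'β + δ_g0 + δ_g1 t_ij + b_0i + b_1i t_ij + ε_ij

* `h` — a strictly increasing parametric link (identity/linear, quadratic
  I-splines on equidistant or quantile knots, or a Beta-CDF family) that
  normalizes the outcome; its Jacobian Σ log h′(y_ij) enters the likelihood.
* `x_i` — class-common covariates: baseline age, sex, neocortical amyloid
  (DVR/SUVR), entorhinal tau (SUVR), eTIV-adjusted hippocampal volume (mm³).
* `δ_g` — class-specific intercept and slope (years from cognitive baseline).
* `b_i ~ N(0, B)` — subject random intercept and slope; ε_ij ~ N(0, σ²).

Random effects integrate out in closed form, so each subject contributes a
mixture of multivariate-normal densities. Candidates over
{4 link families} × {2–7 classes} are estimated with a short-run grid
search (random departures from one-class estimates, burn-in iterations,
best departure polished to convergence). A candidate is admissible if it
converged and every modal class holds ≥ 5% of the sample; among admissible
candidates the favored model minimizes the sample-size-adjusted BIC
(SABIC = −2ℓ + k·ln((N+2)/24)) subject to relative entropy > 0.5.

Downstream, the package compares cognitive-reserve factors across the
labeled subgroups (Kruskal–Wallis + Dunn post hoc with Hochberg
correction; χ²/Fisher for categorical factors), regresses regional tau on
subgroup with Benjamini–Hochberg FDR control, and compares time to
CDR-defined clinical progression with Kaplan–Meier/log-rank analysis.

## Worked example

The real cohorts this design targets are access-restricted, so the package
ships a seeded generator with the same statistical structure. The snippet
below simulates a well-separated three-class cohort, fits the three-class
model and prints the recovered structure:

```python
from crtraj import ModelSpec, build_link, generate_cohort, SyntheticConfig
from crtraj.selection import grid_search_fit, label_classes

cfg = SyntheticConfig.well_separated(n_subjects=300, seed=11)
cohort, truth = generate_cohort(cfg)
fm = grid_search_fit(cohort, ModelSpec(3, build_link("linear")),
                     n_departures=3, burn_iters=25, seed=1)
print("proportions:", fm.class_proportions.round(3))
print("slopes/yr:  ", fm.params.delta[:, 1].round(3))
print("entropy:    ", round(fm.relative_entropy, 3))
print("labels:     ", label_classes(fm))
```

Output:

```
proportions: [0.733 0.057 0.21 ]
slopes/yr:   [-0.013 -0.401  0.009]
entropy:     0.959
labels:      ['Normal', 'Declining', 'Resilient']
```

The generating mixture was 0.70/0.22/0.08 with slopes −0.01/0.00/−0.40 per
year: the fit recovers the mixing proportions within sampling error, the
declining slope almost exactly, and classifies with high certainty
(entropy near 1 means little assignment uncertainty).

The full pipeline (simulate/preprocess → grid search → selection →
labeling → characterization) runs from the command line:

```bash
crtraj simulate --n-subjects 200 --seed 0 --out synthetic/
crtraj run-all --config config.yaml
```

producing a bundle of CSVs (cohort, selection report, per-subject
assignments with posterior probabilities, characteristics and pairwise
comparison tables, survival summary) plus a JSON manifest with seeds and
software versions. Reruns with the same configuration are byte-identical.

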