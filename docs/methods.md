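# Methods

## GMLVQ and the scalar projection

The classifier follows the matrix-relevance formulation of learning vector
quantization: class prototypes w and a full metric tensor Λ = ΩᵀΩ are
learned jointly by stochastic steepest descent on the cost

    E = Σ_i μ_i,   μ_i = (d_J − d_K) / (d_J + d_K),

where d_J is the squared Λ-distance from sample i to the closest prototype
of its own class and d_K to the closest prototype of the other class.  The
transfer function applied to μ is the identity, so per-sample terms lie in
[−1, 1] and the full-batch gradient has the closed form implemented in
`glvq_cost_gradient` (checked against central finite differences in the
test suite, at 1e−5 relative tolerance).

Numerical choices:

* **Standardization.** Features are z-scored with training-sample
  parameters before learning; the same parameters are stored in the fitted
  results and applied to new samples.  The composites, the integer
  depression score, SUVR values and a binary APOE indicator live on very
  different scales, and metric learning converges poorly without this.
* **Initialisation.** Prototypes start at class-conditional means plus
  Gaussian jitter (sd 0.01 in standardized units, seeded); Ω starts at
  I/√D so trace(Λ) = 1 from the first step.
* **Normalisation.** Ω is divided by its Frobenius norm after every
  per-sample update, keeping trace(Λ) = 1 to machine precision; Λ is
  symmetric positive semidefinite by construction.  The diagonal of Λ is
  therefore a relevance profile summing to 1 and the off-diagonals are
  signed interactions.
* **Learning rates and epochs.** Defaults α_w = 0.05, α_Ω = 0.01, at most
  300 shuffled epochs with early stopping once the epoch cost improves by
  less than 1e−6 for 20 consecutive epochs.  These are the model's two
  tunable hyperparameters; the cross-validation layer tunes them on a
  small grid when asked.
* **Tie-break.** A sample exactly on the decision boundary is classified
  stable — the conservative prognosis — making predictions deterministic.

The scalar projection of a sample x (standardized) is

    s(x) = (x − w_s)ᵀ Λ (w_p − w_s) / (w_p − w_s)ᵀ Λ (w_p − w_s).

This is the unique affine score along the prototype axis with s(w_s) = 0
and s(w_p) = 1; the quadratic normalisation (rather than a square root) is
forced by requiring s = 0.5 exactly on the equidistance boundary, which
follows from expanding d(x, w_s) = d(x, w_p).  The score is invariant to
rescaling Λ by any positive constant and is unbounded: values below 0 or
above 1 place a subject beyond the prototypes.  It is defined only for the
linear model (one prototype per class); the operation refuses
multi-prototype models, for which no single prototype axis exists.

## PLS-RFE

The grey-matter biomarker is built by PLS regression (scikit-learn's
NIPALS implementation; predictors mean-centered but not variance-scaled,
since unmodulated densities share a common unit-free scale; response
centered) combined with recursive feature elimination:

* each elimination step removes the 10% of active voxels with the smallest
  absolute total linear coefficient (the per-voxel weight of the fitted
  linear predictor);
* within each of 5 outer folds, a fresh elimination path is run inside
  each of 3 inner folds for every candidate component count (1–3), and
  every iteration is scored on that inner fold's held-out subjects.
  Elimination paths advance in lockstep over a deterministic schedule of
  voxel counts and stop early once the mean inner-validation r² has not
  improved for 3 consecutive iterations;
* the component count and stopping iteration with the best inner
  validation score are replayed on the full outer-training set to give the
  fold's retained voxels and weights;
* the exported map keeps voxels retained by a majority of outer folds,
  with across-fold mean weights, across-fold z-statistics (reporting
  only), and training-mean centers.

Two design points deserve emphasis.  First, elimination is re-run inside
the inner folds rather than once on the outer-training set; scoring a
selection on subjects that contributed to it inflates validation r²
precisely for sets still containing selected noise voxels, and with that
bias present the early-stopping criterion halts far from the informative
set.  Second, the component count is chosen jointly with the stopping
iteration: on spatially correlated noise a second component can look
helpful on the full voxel set while making the elimination path useless,
so choosing it first and eliminating afterwards is unstable.

The grey-matter score of a new subject is the centered weighted sum
Σ_v w_v (x_v − c_v) over retained voxels.  With atrophy loading negatively
on density and memory scores, retained weights are positive and the score
orders groups as cognitively normal > stable MCI > progressive MCI.
`held_out_r2` evaluates each outer fold's subjects with that fold's own
model, so the reported r² is free of selection leakage.

## Validation machinery

* Macro-averaged error is 100 − (TPR + TNR)/2 with the progressive class
  positive; pooled accuracy weights the rates by class sizes.  Reported
  metrics are rounded to one decimal, half away from zero, only at the
  reporting layer.
* k-fold CV is stratified; hyperparameters are selected per outer fold by
  inner stratified CV minimising macro-averaged error.
* Random resampling trains on stratified subsamples of 52 subjects by
  default, correlates held-out scalar projections with decline slopes, and
  reports the median test correlation with a percentile 95% CI plus the
  fitted model attaining the median (for out-of-sample reuse).
* Rates of decline are OLS slopes of score against years since baseline,
  requiring at least three visits.
* Pearson CIs use the Fisher transform; covariate control is implemented
  as a partial correlation (residualise both variables on the covariate
  with an intercept; one degree of freedom lost).  A variable fully
  explained by the covariate yields a partial correlation of 0 by
  convention rather than an error.
* Fisher's r-to-Z compares independent correlations with the
  first-minus-second sign convention; Steiger's Z compares dependent
  correlations sharing an outcome using the pooled-estimate variant of
  Steiger (1980).  Both hold their nominal 5% size under simulated nulls
  in the test suite.
* The outlier rule excludes subjects whose projection exceeds the stable
  mean by more than 2 stable SDs or falls below the progressive mean by
  more than 2 progressive SDs, with thresholds computed once from the full
  input.  Biomarker positivity uses the linearly interpolated 90th
  percentile of the reference group, with strict inequality at the
  threshold.

## Synthetic cohorts

The generator emulates the statistical skeleton of an ADNI-like MCI study:
a latent non-negative severity (gamma-distributed; cognitively normal
subjects draw from a lower-scale gamma, MCI subjects from a shifted one)
drives all observables.  Defaults, chosen once as realistic study
conditions: 300 subjects, one third cognitively normal; a 22³ grid
(≈10⁴ voxels — small enough to run in seconds while preserving the
p ≫ n regime); a spherical planted atrophy region of radius 3 (123
voxels) whose density deficit is linear in severity (0.05 density units
per severity unit on a baseline field of 0.60); smooth spatial noise
(Gaussian kernel σ = 1 voxel, rescaled so the stated per-voxel sd of
0.04 is the sd actually added — smoothing otherwise attenuates white
noise several-fold); memory, executive and depression composites linear in
severity with independent noise; amyloid SUVR rising and APOE4 carriage
more likely with severity; seven visits over four years with jittered
times; memory-decline slopes linear in severity (−0.12 score units/year
per severity unit, noise sd 0.05); conversion times exponential with log
hazard −4.0 + 1.5·severity, follow-up uniform on 3.5–6 years, and the
3-year window rule labelling stable / progressive / excluded (the
hazard intercept puts roughly a third of labelled MCI subjects in the
progressive class); three regional tau values increasing with the
planted-region deficit.

What the generator does **not** emulate: registration and segmentation
artefacts, scanner and site effects, non-linear or non-monotone
trajectories, missing visits, label noise from inter-rater disagreement,
and anatomically realistic atrophy topographies.  Passing recovery tests
on these cohorts therefore demonstrates correctness of the algorithms
under their own assumptions — planted-signal recovery, sign and rough
magnitude of projection–outcome correlations — not clinical performance
on real data.

## Degenerate inputs and edge cases

Zero-variance features are rejected by name before standardization; a
sample coincident with prototypes of both classes raises a degenerate-
sample error; non-finite training cost aborts with the epoch index;
identical prototypes make the scalar projection undefined and raise; an
elimination schedule that would empty the voxel set raises with the
history so far; label assignment requires non-negative conversion times
and flags insufficient observation explicitly.

## Known limitations

Stochastic-gradient GMLVQ training is sequential per sample and seeded,
so fitted models depend (deterministically) on the shuffled sample order;
cohort files are therefore read into a canonical subject order.  The
scalar projection is a linear functional of the standardized features
given Λ; strongly non-linear class structure is out of scope, as are more
than two classes, kernelised or localized-metric variants, and
probabilistic outputs.  The RFE layer assumes a single scalar response;
multi-response PLS and sparsity-penalised PLS are not implemented.
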