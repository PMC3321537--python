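# Methods

This note documents the model, the numerical choices, the synthetic-data
design, and what the test results do and do not establish.

## Model and assumptions

MMTS treats each class as its own reference population. A class's
Mahalanobis space is the triple (μ, σ, Gram-Schmidt triangle) fitted on its
members; distances of an example to each class are computed in each class's
own standardized, orthogonalized coordinates. The implicit assumptions are
those of any Mahalanobis-type classifier: classes are adequately described
by their first two moments, features are on comparable footing after
per-class standardization, and the training members are representative of
the class population. No distributional form is required for the distance
itself, but the screening and validation statistics behave best when the
classes are roughly elliptical.

All standard deviations use the n−1 denominator (feature σ and component
ζ alike). This convention makes two identities exact, both enforced in the
test suite:

* the Gram-Schmidt distance of a full-rank class equals `(1/d)·zᵀR⁻¹z`
  with `R` the ordinary sample correlation matrix;
* the mean of the members' own-class distances is exactly `(n−1)/n`.

Gram-Schmidt processing always follows the cohort's canonical column order
(the clinical schema order for OSA). The unweighted distance is invariant
to feature order; the Stage-4 weighted distance is not, so a pinned order
is required for reproducibility.

## Rank deficiency and the subspace ('drop') mode

A class with n members has centered rank at most n−1, so small classes
cannot support large feature sets at full rank: with 8–23 members per class
and 12 features, some classes are structurally rank deficient, and
orthogonal-array subsets make this routine. Two fitting modes exist:

* **error** (the default for `fit_space`): any component whose ζ falls at
  or below `zeta_floor` (default 1e-8) raises a collinearity error naming
  the feature. This is the right behavior when the caller expects a
  full-rank space.
* **drop** (used by the pipeline for the full model, screening runs, and
  the reduced refit): degenerate components are removed and the distance
  is measured in the spanned subspace.

Drop mode removes a component in two cases: its ζ is at the numerical
floor, or its residual degrees of freedom `n − 1 − (components already
kept)` fall below `min_component_dof` (default 3, capped at n−1 so a class
always keeps at least one component). The DOF rule exists because ζ² is a
variance estimated on those residual degrees of freedom; with 1–2 DOF the
estimate collapses toward zero and a single out-of-sample example can
contribute distances of order 1/ζ² ≈ 10¹⁵, which destroys every downstream
statistic. Three is the smallest integer at which the estimate is usable;
it is a statistical floor, not a tuning parameter.

In subspace mode the distance prefactor `1/d` becomes one over the
retained-component count (identical to d for full-rank fits, so the
printed formulas are unchanged in the normal case). Without this, classes
retaining different component counts produce non-comparable distances and
the smallest class absorbs all predictions. The weighted distance likewise
renormalizes the gain weights over the retained components.

## Validation criterion

The method asks only that abnormal distances be "much larger" than normal
ones. The binding criterion here is `abnormal mean / normal mean >
ratio_threshold` (default 2.0), chosen because it is deterministic and
matches Mahalanobis-Taguchi practice; a one-sided Wilcoxon rank-sum p-value
is reported alongside as a descriptive aid, never as the pass/fail rule.
Validation failure is a reported outcome with the method's prescribed
remedy (revisit the feature set and the representativeness of the
examples); it aborts the pipeline only under `--strict-validation`.

## Screening

The orthogonal array is the smallest Sylvester-Hadamard two-level design
whose column count covers the feature count (L16 for 12 features), factors
assigned to the leading columns in cohort order, level 1 = include.
Balance and pairwise orthogonality are verified by brute force in the
tests. Runs with an empty included set are skipped and excluded from both
SN̄ averages; runs whose subsets exceed some class's rank are scored in
subspace mode and flagged, not discarded.

The signal-to-noise ratio uses exponent 1 on the distance ratios, exactly
as the method defines it; `sn_exponent: 2` switches to the textbook
larger-the-better form. Own-class distances below `md_floor` (1e-12) are
clipped before entering denominators. If no feature has positive gain, the
single best feature is kept and the model flagged degraded, so Stage 4
always has an input.

One caveat on main-effect arithmetic: gains are exactly invariant to how
factors are assigned to columns only when the reassignment maps the run
set onto itself (true for every column permutation of L4; for larger
Sylvester arrays only the linear automorphisms do this). For arbitrary
assignments, interactions alias differently into main effects — ordinary
fractional-factorial behavior, inherited rather than introduced here.

## Small-sample behavior of the screening statistic — a known limitation

η compares member distances to their *own* space (in-sample, mean
`(n−1)/n`) with distances to *other* spaces (out-of-sample, inflated by a
factor that grows with the subset size relative to the class size). Under
a pure-noise cohort at the study's class sizes (8–23 training members, 12
features) this asymmetry makes η increase with subset size, which shifts
*every* feature's effect gain positive: screening at these sample sizes
over-selects, and a null cohort does not produce gains scattered around
zero. The DOF guard reduces the shift substantially but cannot remove it —
it is a property of the statistic's definition, vanishing only as class
sizes grow (or under leave-one-out own-distances, which the method does
not prescribe). The acceptance suite asserts the idealized null behavior
at the study conditions anyway and documents the failure rather than
hiding it; the practical consequence is visible in the worked example,
where several weak features enter the reduced model with small positive
gains. Users applying this package to cohorts of this size should treat
small positive gains as noise and rely on the gain ranking rather than the
sign alone.

For the same reason, under the null the validation separation ratios sit
well above 1 at these sample sizes (out-of-sample inflation), so passing
Stage-2 validation on a small cohort is a necessary but weak check.

## Classification and evaluation

Ties in the minimum weighted distance go to the first class in the declared
severity order (normal < mild < moderate < severe) and are logged.
Evaluation reports per-class accuracy (diagonal over row sum of the
confusion matrix), their unweighted mean (macro-averaged accuracy — the
"Average" arithmetic of the motivating comparison), and the full confusion
matrix; a class with no true examples has undefined accuracy and is an
error to request.

## Synthetic cohort design

The generator reproduces the study's experimental shape, not a patient
population:

* **Schema and anchors.** Twelve features with published cohort-level
  means/SDs/ranges as anchors; class sizes 24/29/19/14; 57/29 stratified
  train/test split (16/23/10/8 training members per class).
* **Severity signal.** The six informative features get class means
  shifted by `effect_size` pooled within-class SDs per severity step,
  centered so the marginal mean stays at its anchor. The within-class SD
  is shrunk so that within- plus between-class variance reproduces the
  anchored marginal SD at every effect size (`s_w = SD/√(1 + e²·Var(c))`),
  so effect size never changes the marginal moments. Default effect size
  is 1.5 — a strong but overlapping clinical signal; 0 is a calibration
  null; 6 an essentially separable regime.
* **Structure kept exact** because the pipeline depends on it: BMI is
  computed as BW/(BH/100)² row by row; weight and height are drawn jointly
  (corr 0.4); the two desaturation indices are drawn as per-class truncated
  normals on [0, 550] through a Gaussian copula (corr 0.95); gender is
  coded 1/2 with an exact per-class female count (marginal mean 1.23); PLM
  has an exact-count point mass at zero (median 0) with a half-normal
  positive part.
* **Degeneracy guards.** Exact counts for the binary/zero-inflated columns
  and truncation (rather than point-mass clipping) for the nonnegative
  indices exist to keep every class's every column non-constant — a
  constant column is unfittable. The stratified split redraws
  (deterministically from its seed, bounded attempts) if a training class
  still ends up with a constant column.
* **What is not emulated.** The heavy right skew of the desaturation
  indices (their synthetic means exceed the published medians by design),
  real feature cross-correlations beyond the two modeled pairs, label
  noise near the RDI band boundaries, and any respiratory-waveform
  structure. Passing tests therefore establish that the *pipeline*
  recovers planted structure of realistic shape and scale — not that the
  published clinical accuracy is reproducible, which would require the
  undeposited patient data.

## Problem sizes and runtimes

The simulation-based checks use 20 seeds at the study's cohort shape
(86 subjects, 12 features, L16 screening = 16 runs × 4 spaces per seed);
the distance-oracle sweeps use 100 random configurations with d ≤ 10 and
n ≥ d + 5. The full test suite runs in well under a minute; the acceptance
script in a few seconds.

## Known limitations

* Screening gain signs are upward-biased at small class sizes (see above);
  the selected set should be read as a ranking, not a hypothesis test.
* Subspace mode measures rank-deficient classes in the subspace their
  members span; distances to such classes are not strictly comparable to
  full-rank classes beyond the per-dimension normalization applied.
* The generator's marginals are Gaussian-with-truncation by design;
  conclusions about robustness to heavy-tailed clinical distributions are
  out of scope.
* No missing-value handling: rows with missing values must be removed
  before fitting, mirroring the original data-preparation convention.
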