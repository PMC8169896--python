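# Methods

This note documents the statistical model behind `morphosus`, the choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not demonstrate about real specimens.

## Landmark protocol and outline semilandmarks

A specimen is an ordered set of p points in k ∈ {2, 3} dimensions with
per-point roles (anatomical landmark vs outline semilandmark).  The dental
protocols are fixed: M/2 = 8 anatomical landmarks + 67 semilandmarks
(p = 75), M/3 = 9 + 99 (p = 108), with the last anatomical landmark lying
on the crown outline and anchoring the semilandmark block.

Semilandmarks are placed at exactly equal arc-length spacing along the
digitized outline polyline (linear interpolation within segments), spacing
perimeter/n for closed curves.  Outlines are normalized to
counter-clockwise winding by the signed-area test before resampling, so
left/right antimeres and y-flipped images produce comparable orderings; a
`flip_y` flag at TPS ingest converts image-convention coordinates.  The
start point must project onto the curve within 2% of total arc length —
enough slack for digitization jitter, with a deterministic failure beyond
it.  Semilandmarks are *fixed* once placed: no bending-energy or
perpendicular-projection sliding is performed during alignment.  This is a
deliberate reading of "equidistant semilandmarks"; a sliding treatment
would change coordinates by a small amount relative to between-group
differences but is out of scope here.

## Superimposition

GPA centers every configuration, scales it to unit centroid size, and
rotates it onto a consensus that is re-estimated each sweep (initialized
from the first specimen, renormalized to unit size), stopping when the
consensus RMS change falls below 1e-10 or after 100 sweeps (non-convergence
is an error, not a warning).  Numerical choices:

* **Rotations only.**  The Kabsch/SVD solver forces det(R) = +1.
  Reflections would silently destroy left/right identity; mirrored
  antimeres should be flipped at ingest instead.  A rank-deficient
  cross-covariance is flagged `ambiguous` and resolved by the deterministic
  SVD sign convention.
* **Partial Procrustes fitting.**  Aligned specimens keep unit centroid
  size (no cos ρ rescaling), and Procrustes residuals are used directly
  without a tangent-space projection: at intra-specific scale the shape
  dispersion is small (Procrustes distances ≲ 0.2), where the projection
  changes distances at the 1e-3 relative level, far below group effects.
* **Form space.**  The form matrix appends ln CS to the shape coordinates
  unscaled.  With CS measured in arbitrary units the log column has spread
  comparable to the shape block for these data; no weighting is applied.

## Permutation tests

Shape data have far more variables than specimens, so all group tests are
Goodall-type: sums of squared Euclidean deviations pooled over all
coordinates, F ratios of mean squares, and significance from permutations.
Parametric MANOVA statistics (Wilks' Λ) are undefined for rank-deficient
within-group covariance and are not provided; printed F values from
parametric software are therefore not comparable.  With one response
column the Goodall F equals the classical one-way F exactly (tested to
1e-9).

* p-values are `(b + 1)/(n_perm + 1)` with `b` the number of permuted
  statistics ≥ the observed one — never zero, smallest attainable
  `1/(n_perm + 1)`.  Default `n_perm = 999`; seeds are mandatory in the
  API and every test reproduces bit-identical p-values for a fixed seed.
* The allometry test permutes the size vector; the group test permutes
  labels; the common-slope (group × size) test compares
  common-slope vs group-specific-slope fits and permutes reduced-model
  residuals (Freedman–Lane), the standard exchangeable quantity under the
  null of a shared slope.
* Sums of squares decompose sequentially (size → group → interaction),
  matching the analysis order: allometry first, then group structure.
* Permutations are vectorized (einsum over a permutation batch), which is
  what keeps the 800-run calibration suite in the test budget.

Type-I error of all four tests is verified at the 0.05 level over 800
seeded null datasets drawn through the full generator + GPA path (observed
rates must fall in 5% ± 2).

## Classification

PCA retains the smallest axis count reaching 95% cumulative variance
(the package default), optionally capped; LDA axes solve the generalized
eigenproblem on between/within scatter in PC space, at most g − 1 axes,
ordered by eigenvalue, with a deterministic sign convention.  Two
implementation choices matter:

* **Well-posedness cap.**  `fit_discriminant` caps the PC count at
  n − g − 1 so the within-group scatter stays invertible — binding in
  two-fold cross-validation, where training halves are small.
* **Scatter shrinkage.**  The within-group scatter is ridged by 1% of its
  mean eigenvalue before the eigensolve.  Near the rank edge the smallest
  scatter eigenvalues are badly underestimated and their inverse dominates
  the whitening; the mild ridge removes that instability while moving
  well-conditioned axes negligibly (≪ 1° on comfortable samples).

Cross-validation is stratified two-fold: each group is split at random
into halves (an odd member alternates sides), PCA + LDA are refitted on
each training fold (no leakage; a `global_pca` switch reproduces
workflows that reduce once on all data), and the held-out fold is
classified by nearest group centroid in LD space under equal priors.
Per-group percentages are averaged over folds and iterations.  Groups
smaller than 2 are an error unless a `min_n` filter (CLI default 4)
excludes them explicitly.  With random labels the expected accuracy is
100/g per group, though any *single* random labeling carries learnable
chance structure of order σ/√n — chance-level checks therefore average
over several permutations.

k-NN ecophenotype prediction uses Euclidean neighbours in LD space,
majority vote, `k = max(1, floor(sqrt(N)))`.  Exact distance ties rank by
lowest training index; vote ties decrement k until resolved (k = 1 cannot
tie) and are flagged.

## Size mixtures

Log centroid sizes are modelled as univariate Gaussian mixtures, fitted by
EM for G = 1..5 under an equal-variance and a free-variance family, model
selected by minimizing BIC = −2 log L + params·ln n (the minimization
convention removes the sign ambiguity of tools that maximize a negated
BIC).  Each candidate starts from 10 seeded k-means-style partitions
(points assigned to G randomly chosen observations); all restarts run as
one vectorized EM for a 40-iteration burn-in, and the best non-degenerate
restart is refined to a log-likelihood tolerance of 1e-8 (500 iterations
cap).  A variance floor of (1e-6 × data range)² prevents division blow-ups,
and — crucially — restarts whose final component sits at the floor or
carries fewer than two effective members are rejected as likelihood
spikes, the classic unbounded-likelihood degeneracy of free-variance 1D
mixtures.  Without that rejection BIC over-selects G on unimodal data.
Components are relabelled by increasing mean so output is deterministic.

## Phenotypic trees

Neighbour joining follows Saitou–Nei agglomeration with the
Studier–Keppler Q criterion and branch-length formulas; ties in Q resolve
to the lowest index pair.  Additive matrices are recovered exactly
(topology and branch lengths; verified to 1e-9 on random trees of ≤ 8
taxa via the tree's exact patristic matrix).  Negative branch lengths are
reported as computed — transparency over silent clamping.  Newick output
carries 6-decimal branch lengths and quotes labels containing spaces or
metacharacters; the exact patristic matrix is kept alongside because the
serialization truncates.  Trees default to *form* distances (mean shape ⊕
mean log size), with a `shape` metric switch, since size is part of the
biosystematic signal the tree is meant to display.

## Synthetic data

The generator is the model GPA inverts.  Specimen i of group g:

    x_i = similarity( T + δ_g + β (s_i − s̄) + ε_i ),   ε_i ~ N(0, σ² I)

with T the unit-size template, δ_g the group mean-shape offset, β the
allometric slope per unit log size, s_i drawn from the group's log-size
model (single normal or two-component mixture), and the similarity
transform a random rotation + translation + scale e^{s_i}.  Offsets and
slope are constructed orthogonal to the similarity modes (translations,
rotations, scaling) at the template, so group means and the allometric
variance fraction are recoverable without similarity-mode leakage; noise
is applied before the transform.  Default noise is σ = 0.01 per coordinate
on a unit-size template — about 1% of configuration scale, the order of
digitization jitter plus within-population dental shape variation.
Templates are deterministic smooth outline-like point sets built through
the same protocol code paths (M/2 75 points, M/3 108, calcaneus 25 in 3D).

Named scenarios fix the study conditions used by the tests: group sizes
follow the published sample accounting where one exists (Klimonas 33,
Shillourokambos middle A 25; the seven modern populations totalling 86
M/2s; calcaneus training classes 56/24/27, N = 107 hence k = 10); the
`allometry-20pct` scenario computes its slope magnitude analytically from
|β|² var(s) = f/(1−f) · σ² · (kp − similarity dof) with f = 0.20.

What passing these tests shows: the implementation inverts its own
generative model at realistic noise, sample sizes and effect sizes, with
calibrated error rates.  What it does not show: robustness to features of
real dental data the generator omits — correlated landmark error, outline
digitization drift, missing/worn cusps (records with missing points are
rejected, not imputed), measurement batch effects, or non-Gaussian size
distributions.

## Problem sizes

Simulation-backed checks use deliberately compact configurations (6-point
templates for calibration loops, 100–200 specimens for recovery checks,
100 seeded runs for mixture selection, 200 cross-validation iterations
instead of the 10,000 a production analysis would use) — large enough for
the stated tolerances, small enough to run the whole suite in minutes on
one core.
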