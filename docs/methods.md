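# Methods

This note documents the statistical model behind `morphdiv`, the parameter
choices that matter, the design of the synthetic-data generator, and the
numerical conventions a user relying on reproducibility should know about.

## Shape variables and superimposition

A specimen is an ordered configuration of `k` 2D points: `f` fixed landmarks
(discrete homologous anatomical loci) followed by outline semilandmarks
organised into open curves. Coordinates are in millimetres once the TPS
`SCALE` factor has been applied; configurations without a scale factor are
accepted with a warning because superimposition removes size anyway.
Specimens photographed from the left side are mirrored about the vertical
axis through their centroid before any analysis; reflections are otherwise
forbidden throughout (all fitted rotations have determinant +1), so
chirality is a real difference the alignment cannot absorb.

Generalized Procrustes alignment (GPA) puts every configuration into
preshape (centred, centroid size 1, where centroid size is the square root
of the summed squared distances of points to their centroid) and iterates:

1. rotate every configuration onto the current consensus by the
   least-squares proper rotation (closed form in 2D);
2. during the first `slide_iter` iterations, slide each semilandmark along
   the chord joining its two slide neighbours to the point minimizing its
   distance to the matching consensus point (an orthogonal projection), then
   re-centre and re-scale;
3. recompute the consensus as the normalized coordinate-wise mean.

Iteration stops when the consensus moves less than `tol` between rounds
(root-summed-squared coordinate change) or after `max_iter` rounds.

**Why sliding is capped** (`slide_iter`, default 5). The projection step
treats position *along* the outline as nuisance and position *across* it as
signal. If the slide/re-mean loop is iterated indefinitely it has no fixed
point on noisy data: because the chord tangent rotates as points move,
semilandmarks creep along the outline and the procedure keeps absorbing
genuine transverse variation (we measured the consensus still moving at the
1e-4 level after 2,000 iterations, with the Procrustes sum of squares
falling a steady ~0.2% per iteration — semilandmark bunching, not
convergence). A small fixed number of passes removes the tangential
component of digitization noise, after which plain GPA converges
geometrically. Results are insensitive to `slide_iter` in the 3–10 range at
the resolution of every statistic reported here; exact numerical agreement
with other morphometrics software is not claimed.

**Gauge fixing.** The Procrustes solution is defined only up to a global
rotation. After convergence the whole set is rotated so the consensus's
principal axis is horizontal, with the residual 180° ambiguity resolved by
the sign of the consensus's third moment along that axis (falling back to
the first landmark's x sign in the perfectly symmetric case). This makes
aligned coordinates a deterministic function of the shapes alone — two runs
on arbitrarily rotated/translated/rescaled copies of the same data agree to
better than 1e-6, which the test suite asserts.

**Defaults.** `tol = 1e-8`, `max_iter = 100`, consensus initialized from the
first specimen in input order. All are overridable; the convergence flag and
per-iteration Procrustes sum of squares are exposed on the fitted estimator
(`ss_history_`), and the sum of squares is non-increasing across iterations.

## Ordination

Per-species mean shapes (coordinate-wise averages of aligned specimens) are
flattened to 2k-vectors and decomposed by PCA on the covariance matrix
(divisor n − 1; covariance, not correlation, because all coordinates share
units). Superimposition removes 4 degrees of freedom in 2D (two translation,
one rotation, one scale), so at most `min(n_species − 1, 2k − 4)` axes are
informative and only those are kept. Axis signs are fixed so each axis's
largest-magnitude loading is positive: distances are sign-invariant but
serialized scores must be byte-reproducible.

Because the retained axes are an orthonormal rotation of the centred species
means, Euclidean distances among full score rows equal distances among
centred mean shapes (asserted at 1e-8 in the tests); this is what licenses
computing disparity in PC space at all. The morphospace used downstream is
the smallest set of leading axes whose cumulative variance share reaches the
threshold (default 0.95, boundary inclusive: an axis landing exactly on the
threshold is retained).

## Disparity and inference

Family disparity is the mean over member species of the Euclidean distance
between the species' scores on the `m` retained axes and the family
centroid (the per-axis mean score of that family — never the global
centroid), with standard error `sd(distances)/sqrt(n)`. A formulation that
divides a single square root by `n` rather than averaging per-species
distances appears in some write-ups of this statistic; we implement the
mean-of-distances reading, which is the one consistent with "mean Euclidean
distance to the centroid" and with per-species distances being meaningful
quantities in their own right (they feed the Welch test below).

Three complementary comparisons:

* **Welch t** (Satterthwaite df, two-tailed) on the two families'
  per-species distance samples, via `scipy.stats.ttest_ind(equal_var=False)`.
* **Label-permutation test**: the family labels are reshuffled uniformly
  (group sizes preserved — with 12 species labelled "golden mole" in every
  shuffle, unequal sample sizes are accounted for automatically), both
  centroids and disparities are recomputed, and the difference recorded;
  default 1,000 shuffles. Two-tailed p by absolute-value comparison with the
  add-one correction `p = (1 + #{|null| ≥ |obs|}) / (n_perm + 1)`; the null
  minimum and maximum are reported alongside.
* **PERMANOVA** (non-parametric MANOVA) on the retained-axis scores:
  `SS_total = Σ_{i<j} d²_ij / N` partitioned into within- and between-group
  components, pseudo-F = `(SS_b/(a−1)) / (SS_w/(N−a))`, significance from
  whole-row label permutations (default 999, so the smallest attainable p is
  1/1000). In the univariate limit pseudo-F equals the classical one-way
  ANOVA F exactly; the implementation is cross-checked against
  `vegan::adonis2` in the test suite.

All permutation draws come from one `numpy.random.default_rng(seed)` per
test invocation and the seed is recorded in the result object.

## The synthetic-data generator

The generator emulates the sampling structure a two-family cranial disparity
study assumes, not skull anatomy per se. Shape variation lives in a
three-parameter deformation space — rostral elongation, cranial width,
braincase doming — applied to smooth parametric skull templates
(superellipse braincase plus a tapering rostrum; a domed profile for the
lateral view). Working in a low-dimensional parameter space, rather than
adding independent per-landmark noise at the species level, concentrates
between-species variance on a few principal axes, as real cranial data do.
Per-view structure: dorsal 10 landmarks + 44 semilandmarks on 4 curves,
ventral 13 + 60 on 4 curves, lateral 9 + 35 on 2 curves; every curve runs
between two fixed landmarks and every semilandmark gets a slider triple.

Hierarchical sampling, fully reproducible from one seed:

* species mean parameters = family mean + Gaussian species effect
  (`species_sd`); an optional cluster of species is drawn around
  `family mean + cluster_offset` with the much smaller `cluster_sd`;
* specimen = species template + isotropic Gaussian digitization noise
  (`digitization_sd`, in mm) + a random similarity transform (rotation,
  translation, lognormal size jitter) and, for a random `left_side_fraction`
  of specimens, a mirror flip flagged `side=left` in the specimen table;
* TPS output is written in pixel units with a per-specimen `SCALE` factor
  (mm/pixel), as a digitizer would produce.

The truth record stores every latent species parameter and each family's
noiseless shape-space dispersion, so parameter recovery can be scored.

**Default study frame** (chosen once, to mirror a realistic two-family
design, and documented rather than tuned): a 31-species family containing a
19-species cluster versus a 12-species family; specimens per species uniform
on 1–21; `species_sd = 0.05` and family mean parameters
(0.9, 0.55, 0.35) vs (0.78, 0.61, 0.41), which place the families apart at a
between:within ratio typical of real cranial interfamily comparisons
(PERMANOVA R² around 0.5–0.7) while producing within-family disparities of
order 0.01–0.02 in Procrustes units; cluster offset (0.08, −0.03, −0.02)
with `cluster_sd = 0.012`, i.e. a distinct but nested morphotype — the
regime in which over-sampling a uniform genus masks family-level disparity;
`digitization_sd = 0.1` mm on a ~35 mm skull (≈0.3% of size, a typical
digitization error); size jitter sd 0.05; pixel scale uniform on 0.02–0.05
mm/px; left-side fraction 0.25.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real data: allometry (shape–size covariation is absent
by construction), asymmetric or autocorrelated digitization error,
phylogenetic covariance among species effects, missing or damaged landmarks,
within-species biological variation distinct from measurement error, and the
high-dimensional residual shape variation of real skulls (real analyses
retain 6–7 axes at the 95% threshold where the three-parameter generator
typically yields 2–3).

## Numerical conventions and degenerate inputs

* Slider chords of zero length leave the semilandmark in place with a
  warning; a rank-zero cross-covariance in rotation fitting returns the
  identity with a warning.
* Zero-variance score sets: the axis-selection rule is undefined, so one
  (zero-variance) axis is retained by convention; the pipeline zeroes
  numerically-noise-only scores (total variance below 1e-15 of the mean
  squared shape norm), after which disparities are exactly 0, the
  permutation p is exactly 1, and Welch/PERMANOVA are reported as NaN
  rather than computed from round-off noise.
* PERMANOVA on exactly identical observations raises (`SS_total = 0`), as
  does Welch's t when both samples have zero variance.
* The permutation comparison uses a 1e-15 absolute slack so exact ties
  (e.g. an all-zero null) count as extreme.
* The outline-economy scan returns the first `n` whose inscribed-chord
  length ratio reaches the accuracy target; for non-convex curves the ratio
  need not be monotone in `n` and the first satisfying `n` is returned as
  specified. The dense input curve is treated as the true outline, so it
  should be sampled well above the resolution being sought.
* CSV outputs are written with pandas' default float formatting
  (shortest-round-trip), making re-runs with identical inputs and seeds
  byte-identical; the test suite asserts this.

## Problem sizes used by the test suite

The simulation-backed tests run at deliberately compact sizes chosen to give
stable verdicts: type-I error calibration uses 200 null datasets at the
31-vs-12 and 17-vs-12 species frames with 499 permutations each; dispersion
ratio recovery uses 20 replicate studies of 20 + 20 species × 5 specimens;
the masking contrast uses 20 replicate 31-species studies at 3 specimens per
species. The acceptance script runs the full default frame (three views,
~450–500 specimens per view, 1,000/999 permutations) in a few seconds.

## Known limitations

* 2D only; no 3D alignment, no bending-energy sliding, no estimation of
  missing landmarks, no bilateral-symmetry decomposition.
* Disparity is the mean distance to the family centroid; variance-based,
  convex-hull or phylogenetically rate-based disparity measures are out of
  scope.
* The subset re-analysis drops species by genus membership inferred from the
  leading underscore-delimited token of the species name; datasets using a
  different naming convention should pre-filter explicitly.
* Exact numerical agreement with other GPA implementations is not expected:
  sliding schedules, convergence criteria and rotational gauges differ
  between packages, and agreement is at the level of the statistics
  (disparities, F, p), not raw aligned coordinates.
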