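# Methods

This note records the model, the numerical choices, and the
limitations of the `tractmsa` pipeline, in the order data flows
through it.

## Disconnection metric

Per patient and tract, damage is the set-cardinality overlap
`d = |lesion ∩ bundle| / |bundle|`, computed after binarizing the
tract's probability map at a threshold (default 0.5, configurable).
Voxels are unweighted counts: a probability-weighted overlap would be
a different, smoother metric, but the set form keeps `d` exactly
reproducible by brute-force counting, which the test suite exploits as
an oracle.  Lesion masks must already be registered to the atlas grid;
no resampling is attempted, and a grid mismatch is an error rather
than a silent interpolation.

The rest-of-brain (RoB) player aggregates the pool of bundles outside
the player set: its fraction is the lesioned share of the union of
pool masks, with voxels that also belong to a player tract removed
from both numerator and denominator.  The alternative — counting
overlap voxels against both a player and the RoB — would let a single
lesion voxel influence two players at once; the exclusive reading was
chosen so the RoB remains a pure omitted-contributor guard.  A high
RoB contribution flags that relevant tracts were left out of the
player set; it is reported but excluded from contributor
classification by default.

Lesion-covariance diagnostics are pairwise Pearson correlations of the
per-tract damage columns across patients, with two-sided p-values;
entries at p ≥ .05 are masked, and a zero-variance tract yields NaN
rows flagged as undefined rather than silently zeroed.

## Test scoring and binarization

* Line bisection: raw scores arrive as mean percent deviation of
  20 cm lines, so mm = pct/100 × 200.  Deficit iff mm > +6.5 or
  mm < −7.3, both strict — "larger/shorter than" is read literally, so
  a score exactly at a cut-off is normal.
* Bells cancellation: laterality = right − left found targets (max 15
  per side); deficit iff |laterality| > 2, strict.
* Letter cancellation: laterality = right − left *omissions* (max 30
  targets per side); deficit iff |laterality| > 2, strict.  The
  age-conditional norm collapses to the same rule for this cohort's
  age range.

Because the coalition analysis needs a score that grows with ability,
the deficit label is inverted: performance = 1 − deficit.  Per-test
subcohorts are formed from score missingness inside the pipeline
(23/24/19 of 25 patients in the reference table), never by
pre-filtering input files.

## Predictor as characteristic function

A support-vector classifier with box constraint c = 1 is trained per
test on the graded intactness matrix (patients × players, values in
[0, 1]) with performance labels.  Kernel defaults per test: linear for
line bisection, polynomial for bells, quadratic for letter.
"Quadratic" is implemented as a degree-2 polynomial kernel and
"polynomial" defaults to degree 3 (the common library default); both
degrees are configurable and `kernel_scan` reports leave-one-out
accuracy across all three families.  No class weighting is applied.

Validation:

* **Leave-one-out accuracy** — each patient held out in turn.  A fold
  whose training labels collapse to one class cannot fit an SVM; it
  falls back to the training-fold majority class with a logged
  warning.
* **Chance level** — each case is compared against a randomly drawn
  score of *another* case, averaged over shuffles; this converges on
  the closed form Σₖ nₖ(nₖ−1)/(n(n−1)) for class counts nₖ, which is
  also exposed directly for testing.
* **Youden index** — sensitivity + specificity − 1 of the LOO
  predictions, undefined (error) for single-class labels.

Binary perturbation configurations are evaluated as intactness
vectors, so a patient whose graded vector happens to be binary gets
the same label through either path.  Note the corners of the cube are
extrapolations for a predictor trained on mildly lesioned cohorts: if
lesions barely dent any tract, the induced game can degenerate to a
constant at the corners.  The synthetic generator's defaults avoid
this regime (below).

## Shapley estimation

* **Exact**: full enumeration of the 2^M configurations (refused above
  M = 20), with the standard factorial weights.  Efficiency
  (Σφ = v(full) − v(empty)) holds to machine precision; symmetry and
  the dummy axiom are exercised on constructed games in the suite.
* **Estimated**: orderings sampled uniformly with replacement; each
  player accumulates v(predecessors ∪ {i}) − v(predecessors) with all
  later players perturbed.  The estimate is the mean over sampled
  orderings and the SE the across-ordering standard error.  Every
  single ordering telescopes to v(full) − v(empty), so efficiency
  holds exactly for any sample size.  Configurations are cached under
  integer bitmasks, and for M ≤ 16 the predictor is pre-tabulated on
  all configurations, making the estimator lookup-bound.
* **Bootstrap**: patients resampled with replacement at original size,
  predictor retrained, estimator rerun (defaults: 1,000 resamples ×
  1,000 orderings).  Resamples with single-class labels are redrawn
  (capped at 100 consecutive attempts) rather than skipped, keeping
  the resample count fixed.  Both dispersion readings are kept: the SD
  of the per-resample estimates (the error bars of the contribution
  plots) and the averaged within-resample SE.

Normalization divides by Σ|φ| (signs preserved, |normalized| sums
to 1) so magnitudes are comparable across tests; division by the raw
sum — the efficiency total — is available as an alternative mode.
Significance uses the central (1 − α) bootstrap percentile interval
(α = 0.05 default): a player is significant iff the interval excludes
zero.  Fewer than 20 resamples make the percentile interval too coarse
and the result is marked unreliable.  A player is task-invariant
positive (negative) when significant with that sign in every test;
anything else is task-dependent with per-test signs reported.
Pairwise interaction terms between players are deliberately not
computed.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis needs,
not anatomy:

* **Atlas** — isotropic Gaussian probability profiles around
  best-candidate-separated centres on a 16³ grid; the supra-0.5 core
  is a ball of radius ≈ 2.4 voxels (15 % of the smallest grid extent).
  Default player set: 11 tracts named after the visuospatial-attention
  bundles, plus 4 pool tracts forming the RoB, i.e. 12 players.
* **Lesions** — 6-connected region-grown blobs from uniform seed
  voxels; extents lognormal with median 300 voxels, σ = 0.5 (truncated
  at the grid volume).  These defaults make per-tract damage span most
  of [0, 1] across a cohort — as real chronic stroke cohorts do, where
  maxima near 90 % damage are reported — while keeping most pairwise
  damage correlations below 0.5, the regime reported for real
  lesion-pattern covariance.  Substantially smaller lesions leave the
  binary corners of the predictor cube unconstrained and the induced
  game degenerate.
* **Behavior** — latent performance w·intact + N(0, σ); the outcome is
  normal iff the latent exceeds a threshold placed at the 0.45
  quantile of the noiseless latent, giving realistic deficit rates.
  This linear-threshold rule is the minimal model under which each
  player's true contribution has a known sign and rank, making
  recovery measurable.  The benchmark weight vector
  (`RECOVERY_WEIGHTS`) spans strong-to-weak positive weights, three
  negative contributors, and a small positive RoB weight.
* **Raw scores and missingness** — raw test scores are drawn
  consistently with the generated label (so a round trip through the
  scoring module reproduces the labels exactly), and per-test
  missingness is injected completely at random, by default matching
  the 23/24/19-of-25 completion pattern.  Each patient is guaranteed
  at least one completed test unless explicitly allowed otherwise.

What the generator does *not* emulate: vascular-territory lesion
geometry, spatial autocorrelation of real atlases, registration error,
or any anatomical plausibility of tract placement.  Passing tests
therefore demonstrate correctness of the estimation machinery under a
known ground truth, not clinical validity on real imaging.

## Problem sizes in the validation suites

The test-suite and acceptance computations are sized to run on one
CPU in a few minutes: axiom checks use 1,000 random 2–8 player games;
estimator-vs-enumeration uses a single 12-player predictor-backed game
(4,096 configurations) with 10 replicate estimates per permutation
count; ground-truth recovery uses one 200-patient cohort with 100
bootstrap resamples of 200 sampled orderings; the reference-scale
study uses n = 25 with the full 1,000 × 1,000 sampling.  Sign recovery
is asserted for weights with |w| ≥ 0.2 — weaker players sit below the
noise floor at these sample sizes.

## Known limitations

* With ~25 patients the SVM validation statistics are themselves noisy;
  single-seed leave-one-out accuracies on synthetic 25-patient studies
  range widely around their expectation, which is the reason the
  recovery guarantees are stated at n = 200.
* The characteristic function inherits every bias of the predictor;
  kernels other than linear can make corner extrapolations
  non-monotone in individual players.
* The printed age SD of the reference cohort (10.63) differs in the
  last digit from the value recomputed from the printed integer ages
  (10.62, n−1 denominator); summaries report the recomputed value.
* Registration, bias correction, and lesion delineation are out of
  scope: masks are consumed as given, on the atlas grid.
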