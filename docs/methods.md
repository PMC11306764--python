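# Methods

`suturemorph` quantifies the morphology of infant cranial sutures and
fontanelles from 3D border curves and builds a regression-based
statistical shape model on top of that quantification.  This note
documents the models, the numerical choices, and what the synthetic
test harness does and does not show.

## Input representation and coordinate conventions

All geometry is in millimetres in a right-handed frame with X =
left→right, Y = posterior→anterior, Z = inferior→superior, so the
superior cranial surface is a height field over X–Y.  The frame is a
package convention (stored as a tag on every `BorderCurveSet`, never
silently assumed); Slicer FCSV files in the LPS dialect are converted
on read by negating X and Y.  No unit autodetection is performed.

A subject is seven ordered border polylines following a fixed topology:
borders 1/2 are the right/left frontal-bone medial edges starting at the
nasion (metopic suture → anterior-fontanelle edge → coronal suture);
borders 3/4 are the parietal-bone edges, open loops starting and ending
at the parietal corner point (sagittal → posterior fontanelle →
lambdoid → mastoid fontanelle → squamosal → sphenoidal fontanelle →
coronal → anterior-fontanelle edge); borders 5/6 are the temporal
superior edges; border 7 is the occipital superior edge between the two
asteria.  Each border is uniformly resampled by arc length to a fixed
semilandmark count — 100/100/200/200/50/50/100, 800 points in total.

## Junction detection

Thirty-two junction points partition the borders into nine named parts
(five sutures, four fontanelle groups).  Two sit at the nasion, two at
the parietal corner points; the rest are detected from width-change
criteria:

* **Metopic→anterior fontanelle and sagittal→posterior fontanelle**
  (k-criterion): scanning the *paired* width series `w_i` between the
  left and right borders from the suture's start, index `i` qualifies
  when `w_{i+1} − w_i > k` and `w_{i+1} − w_i > 10·k·(w_i − w_{i−1})`;
  the junction is the last qualifying index.  Defaults `k = 0.15` mm
  (metopic) and `k = 0.18` mm (sagittal).  The second clause's algebraic
  reading (the current increment dominating the previous one) is one of
  two plausible parses of the criterion; an absolute-value variant is
  available behind `JunctionConfig.strategy`.
* **Lateral junctions** (m-criterion): indices where the second-order
  width change `(w_{i+1} − w_i) − (w_i − w_{i−1})` exceeds `m = 0.4` mm,
  with each run of consecutive qualifying indices reduced to its last
  index.  The width series here is, per border, the nearest-point
  distance to the union of all other borders — a package choice, since
  no canonical pairing exists for the lateral borders.  A suture
  running parallel to its partner keeps this series flat; every opening
  into a fontanelle produces a kink, so the nine-part boundaries emerge
  as second-difference spikes.

Two scan guards make the k-criterion robust rather than sensitive to
how far a border continues past its fontanelle: the paired scan stops
once the width first exceeds `flare_stop_ratio` (default 1.4) times the
median width of the leading quarter of the series — i.e. just after the
fontanelle flare has clearly begun — so later width jumps (fontanelle
corners, lateral sutures) cannot out-vote the flare onset.  If the
series never exceeds that level there is no fontanelle and the junction
is reported as not found.

Indices are 0-based internally; part ranges are half-open and disjoint
within each border, with the shared junction point re-attached when a
side polyline is extracted for measurement.

## Morphometrics

* Suture **length** = mean of the two sides' polyline arc lengths;
  bilateral sutures (coronal, squamosal, lambdoid) report the sum of
  their left and right branches, each branch being a two-side mean.
* Suture **width** = mean per-semilandmark gap; the metopic and
  sagittal use the paired rule (i-th point to i-th point), the
  asymmetric lateral sutures the nearest-point rule.
* **Sinuosity index** = arc length over endpoint chord per side,
  averaged over sides, with the chord taken between each side's own
  junction endpoints.  SI ≥ 1 by the triangle inequality; on a curved
  vault even a wave-free suture carries a curvature baseline of about
  1.03–1.10, and interdigitation adds on top of it.
* **Cranial parameters**: length L = glabella–opisthocranion distance,
  width W = eurion–eurion distance, circumference C = arc length of the
  closed axial head contour (warning if the contour passes more than
  2 mm from glabella or opisthocranion; C is reported missing, never
  extrapolated, when no contour is supplied).

## Surface areas

The suture/fontanelle system is reconstructed as five thin-plate-spline
height-field patches: superior over X–Y, left and right lateral over
Y–Z, anterior and posterior over Z–X.  Patch membership assigns each
part to exactly one patch (superior: metopic, anterior fontanelle,
sagittal, posterior fontanelle; anterior: coronal; posterior: lambdoid;
each lateral: its squamosal branch plus the sphenoidal and mastoid
fontanelles), so areas sum without double counting.  The TPS is the
interpolating spline (kernel r²·log r with an affine tail, zero
smoothing by default); duplicate projections are merged by height
averaging and collinear projections rejected.  Each part footprint —
a strip between suture sides, or a fontanelle boundary loop ordered by
angle about its centroid — is sampled on a staggered triangular lattice,
Delaunay-triangulated in the base plane, lifted through the spline and
summed with Heron's formula.  The in-plane spacing is divided by the
patch's mean metric factor `sqrt(1 + |∇h|²/2)` so the mean 3D triangle
edge tracks the 0.3 mm default target even on steep patches.  Degenerate
triangles (negative Heron radicand beyond round-off) are excluded and
counted; a degenerate patch is reported missing and the total flagged
partial rather than failing the subject.

## Alignment and sliding

Subjects are first rigidly aligned to a user-designated reference by a
closed-form least-squares fit of the (rhinion, fmoR, fmoL) triplet —
proper rotation plus translation, no scaling; a reflection-optimal
correspondence falls back to the best proper rotation with a warning.
Generalized Procrustes Analysis then runs in *form space*: iterative
translation to a common centroid and rotation to the evolving
consensus, never scaling, so each subject's centroid size is preserved
exactly (convergence when the consensus moves less than 1e-10 RMS, cap
100 iterations).

Semilandmarks are then relaxed by bending-energy sliding: with the
bending-energy matrix of the TPS anchored on the consensus (3D kernel
U(r) = −r, affine tail), each non-anchor point may move along its local
curve tangent (central difference of its border neighbours), and the
tangential steps of all sliding points are obtained from one linear
solve that minimizes the subject's summed per-axis bending energy
against the consensus.  Points are then hard re-projected onto their
source border polyline, and a backtracking halving of the step absorbs
any energy increase caused by re-projection, so the energy is
non-increasing at every iteration by construction.  Anchors (border
endpoints, optionally junction points) never move.  Three iterations by
default, with GPA re-run between iterations; with `realign=False` the
shapes are treated as already superimposed and anchors stay bitwise
fixed.  Sliding for curves only; surface semilandmarks are out of
scope.

## Standardization, dimension reduction and comparison

Subjects enter the statistical stage as rows of the N×2400 raw
coordinate matrix.  Standardization z-scores each column with the
population (divide-by-N) SD — a pinned convention — storing the
mean/SD pair for exact inversion; zero-variance columns pass through
flagged.  Classic PCA is computed by SVD of the standardized matrix
(numerically preferable to forming the covariance), with component
signs fixed so each component's largest-magnitude loading is positive.
Reconstruction maps scores through the basis and inverse
standardization back to millimetres, where the location mean deviation
(LMD) — the mean Euclidean distance between corresponding points — is
the universal error measure.

Kernel PCA (linear, cosine, rbf, sigmoid, laplacian; gamma defaults to
1/n_features) reconstructs through scikit-learn's kernel-ridge
pre-image map so its LMD is computable on the same footing.  The
variational autoencoder is a fully-connected architecture written in
NumPy (tanh hidden layers, reparameterized sampling, Gaussian
reconstruction term plus analytic KL, full-batch Adam); it is
bitwise-deterministic for a fixed seed and trains comfortably on CPU at
the sizes used here.

The comparison harness is 10-fold cross-validation with near-equal
random folds (69 subjects split 9×7 + 1×6).  Standardization is fitted
per fold on the training subjects only; held-out subjects are
projected, reconstructed and inverse-standardized before LMD is
measured.  The requested component count is clamped to the per-fold
feasible rank; a method failure marks its cells NaN and the run
continues.

## Regression shape model

PC scores are regressed on standardized morphometric covariates (any
subset of L, W, C, total surface area S, and the average SI of the five
sutures; intercept included by default) through the Moore–Penrose
pseudoinverse — the least-squares coefficient matrix, robust to the
near-collinearity of L, W and C.  The component count defaults to the
smallest k explaining 95 % of the variance; the threshold, not the
count, is the primitive.  Prediction is deterministic and affine;
covariates outside the training range predict with an extrapolation
warning.

Evaluation is leave-one-out: each fold refits standardization, PCA and
the regression without the held-out subject and predicts it from its
own measured covariates, reporting overall LMD, per-part LMD over the
subject's own nine-part partition, and predicted-versus-measured suture
length/width/SI.  Per-PC/per-covariate significance uses one OLS per
cell with the F-test p-value (stars at p < 0.001 and p < 0.0001); no
multiple-testing correction by default, Bonferroni available.
"Percentile infants" use elementwise (marginal) empirical covariate
percentiles — a reproducible convention, since joint percentiles are
not uniquely defined — and the size table is normalized by its
5th-percentile row.

## The synthetic generator

The generator exists so that every stage is testable without
restricted-access CT data.  It lays the seven-border topology onto a
half-ellipsoid vault (half-axes 53.515/62.72/65 mm, giving cranial
length 125.44 mm, width 107.03 mm and circumference ≈ 366.8 mm at
baseline — population values for 2–4-month infants), with:

* a midline chain nasion → metopic (52 mm) → rhombic anterior
  fontanelle (30×25 mm diagonals) → sagittal (91 mm) → posterior
  fontanelle (16×14 mm);
* bilateral coronal (65 mm) and squamosal (58 mm) sutures solved by
  bisection to their target lengths, joining sphenoidal (7 mm) and
  mastoid (6 mm) fontanelle openings with free-edge stubs; the lambdoid
  length is emergent (~37 mm per side on this vault geometry — shorter
  than a real lambdoid, a known simplification of the single-ellipsoid
  vault);
* suture widths 1.54/5.45/1.88/2.24/2.62 mm
  (metopic/sagittal/coronal/squamosal/lambdoid);
* in-phase sinusoidal interdigitation (both sides wave together, so the
  gap stays at the nominal width while SI rises), tapered to zero at
  suture ends; amplitudes/wavelengths of 0.35/12, 1.2/14, 0.45/14,
  0.4/14 and 0.5/15 mm give SIs of roughly 1.03–1.17 with the sagittal
  the most tortuous;
* an explicit linear width flare where the lambdoid opens into the
  posterior fontanelle (a funnel whose onset *is* the junction), and
  perpendicular-arrival stubs at free fontanelle edges — both so the
  width-change criteria see crisp, single-sample kinks at the true
  junctions.  Ground-truth junction ordinals are recorded at these
  construction boundaries; at the default thresholds detection recovers
  all 32 within one semilandmark ordinal across hundreds of subjects.

Per-subject variation is exactly linear in three latent factors — size
(6 % proportional scale per SD, matching an ~6 % cranial-length CV),
fontanelle area (7 % diagonal growth per SD) and interdigitation
amplitude (30 % per SD) — via displacement fields obtained by
differencing perturbed templates built in exact point correspondence.
Latents are clipped at ±2.5 SD to exclude anatomically implausible
tails (e.g. near-closed fontanelles).  The size field carries most of
the coordinate variance, so the leading raw principal axis tracks the
size latent (|r| > 0.99 noiselessly).  The area effect is deliberately
the smaller of the two shape factors so that this dominance holds by
construction.

Because arc-length resampling does not commute with the displacement
fields, the generator emits two consistent representations: the dense
border curves (input to the tracing/junction pipeline) and an
exact-linear semilandmark product built from per-template resampled
points — the representation on which a noiseless population is exactly
rank 3 and regression ground truth is exactly recoverable.

Tracing noise is modelled as a smooth correlated displacement field
(SD 0.1 mm, 10 mm correlation length along the border) rather than iid
point noise: manual tracing errors are spatially correlated, and white
noise of the same magnitude would saturate the second-difference
criterion that the junction method depends on.  Noise is added only
after all ground truth has been measured.

What passing tests on this generator do *not* show: the vault is a
single smooth ellipsoid (no bone plate curvature discontinuities,
no overlapping plate edges), interdigitation is a single-frequency
sinusoid rather than the fractal-like pattern of real sutures, the
latent space is 3-dimensional and exactly linear, and fontanelle
shapes are idealized rhombi/funnels.  Results on real CT-derived
borders will see noisier width series and richer shape variance;
the configurable thresholds exist for exactly that reason.

## Problem sizes and numerical choices

The default test and acceptance runs use populations of 10–30 subjects
with the full 800-semilandmark representation, 0.3 mm triangulation on
analytic oracles and full-subject patches, 10-fold cross-validation,
and 500 replicates for the null-calibration check; these sizes keep a
complete run in minutes on one CPU while exercising every code path at
full resolution.  Tolerances follow the quantity: interpolation and
linear-algebra identities at 1e-8–1e-12, quadrature-based geometry
oracles at 0.1–1 %, stochastic checks at 2 standard errors.  Ridge
fallbacks (1e-10, escalating on singularity) stabilize the sliding and
bending-energy solves; eigenvalue warnings from the sigmoid kernel are
suppressed as expected behaviour of an indefinite kernel.

## Known limitations

* Patch membership for the five TPS patches is fixed by part, not by
  split indices within parts; transition zones between patches follow
  the part boundaries.
* The lateral-junction width series (nearest distance to the union of
  other borders) is one documented choice among several possible
  pairings; alternative pairings can be supplied by calling
  `find_lateral_junctions` directly.
* Sliding relaxes along curves only, and the interleaved-GPA mode can
  move anchors rigidly (use `realign=False` for strictly fixed
  anchors).
* The regression model is strictly linear by design; no nonlinear
  variants are provided.
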