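# Methods

`beadct` characterizes the 3D morphology of microcarrier beads — the
100–300 µm particles used as attachment substrates for adherent-cell
expansion in stirred bioreactors — from micro-CT and contrast-enhanced
micro-CT (CE-CT) volumes. This note describes the models and procedures the
package implements, the assumptions behind them, the synthetic data used to
validate them, and the numerical choices that make results reproducible.

## Imaging model and binarization

Hydrated beads have a physical density close to water, so CE-CT relies on a
contrast-enhancing staining agent (a high-atomic-number compound) that
either binds the bead matrix (*positive staining*: bead brighter than the
suspension liquid) or stains only the liquid (*negative staining*: bead
darker than the liquid but brighter than air). In both regimes the gray
histogram has three peaks — two background phases (air and liquid) and one
bead phase.

Binarization is therefore three-class Otsu thresholding with two thresholds
`(t_low, t_high)` maximizing between-class variance. The optimum is found by
exhaustive search over all threshold pairs of the discrete histogram (native
integer bins for 8-bit data, 256 equal-width bins otherwise), so it is exact
rather than approximate; a property test checks it against a brute-force
triple loop, and the class partition agrees with scikit-image's independent
implementation to ≥ 99.9 % of voxels on noisy phantoms. Foreground is the
class above `t_high` for positive staining and the middle class
`(t_low, t_high]` for negative staining. Threshold boundaries are inclusive
on the lower side of each upper class (`gray > t` is the upper class) so
tests can be bit-exact.

Pre-analysis housekeeping: a circular region-of-interest clears the sample
container from every slice (a voxel is kept when its in-slice center
distance is ≤ the ROI radius), and volumes can be resized by integer-factor
block averaging, which preserves the three-peak histogram structure that
the binarizer needs. Grids are isotropic; all public quantities are in µm,
µm², µm³. Arrays are ordered `(z, y, x)` with z the slice index.

## Spherical beads: 3D Hough transform

For spherical carriers the per-bead model is a sphere with center **c** and
radius R, detected by a gradient-voting Hough transform:

1. Edge voxels (gradient magnitude of the Gaussian-smoothed volume above a
   fraction `edge_threshold` of the maximum) vote along their ±gradient
   directions at every candidate radius between R_min and R_max. R_min and
   R_max are dataset inputs, in practice taken from the manufacturer's
   size range.
2. Per-radius vote maps are Gaussian-smoothed and normalized by the
   theoretical shell support (∝ r²), making scores comparable across radii;
   candidate centers are local maxima above `accumulator_threshold`,
   deduplicated by greedy non-maximum suppression with a minimum center
   separation (default R_min). Voting runs on a block-averaged working grid
   (default factor 2) for speed.
3. Each candidate is refined on the full-resolution edge map: edge voxels
   with near-radial gradients (|cos| > 0.8, which rejects neighbouring beads
   and the container wall) are weighted by gradient magnitude and fit with
   an algebraic least-squares sphere, iterating the radial window. Because
   the gradient-magnitude peak of a Gaussian-smoothed convex boundary sits
   about σ²/R inside the true surface (verified numerically on noiseless
   digitized balls), the final radius receives a `+σ²/R` curvature
   correction.

Per-bead surface area and volume then follow the closed forms 4πR² and
(4/3)πR³, and binary spherical shells (default thickness 10 µm) built from
the fitted centers/radii provide visual quality-control overlays. On the
five-sphere benchmark the detector recovers every bead with center errors
< 0.5 voxel and radius errors < 0.5 voxel, putting model volumes within 5 %
of the voxel-count volumes.

## Non-spherical beads: six-step segmentation

Porous or concave carriers touching each other are isolated by a six-step
pipeline (parameters V_small, R_p, R_op, R_cl are per-dataset,
acquisition-dependent settings exposed as configuration):

1. three-class Otsu binarization with staining-aware foreground selection;
2. removal of foreground connected components (3D 18-connectivity) smaller
   than V_small (noise speckle);
3. Euclidean distance transform of the background thresholded at > R_p
   (half the largest pore-throat thickness), which disconnects pore
   channels from the background;
4. morphological opening with a discrete spherical element of radius R_op,
   detaching remaining thin background tendrils;
5. clearing of background components not touching the volume border (these
   are the pore interiors), then dilation of the surviving true background
   by R_p back to the bead boundary — the complement is the bead mask with
   open pores sealed and closed pores filled;
6. watershed splitting: the Euclidean distance transform of the sealed mask
   is Gaussian-filtered with σ = `gaussian_sigma` voxels (default 7) and
   its local maxima become the bead markers — the smoothing merges the
   spurious maxima digitization creates, preventing oversplitting; flooding
   then runs on the negated *unsmoothed* distance transform restricted to
   the foreground, so the cut between touching beads falls on the true
   neck (flooding the smoothed surface instead displaces the cut by up to
   ~σ voxels, which shaves caps off beads and was measurably the dominant
   porosity error on touching pairs). Basins are flooded jointly (no
   watershed lines remain) and labels are renumbered in scan order so
   reruns are identical.

Non-porous beads imaged with negative staining use a variant: steps 3–5 are
replaced by a morphological closing of radius R_cl plus filling of small
background ("black") components below a cutoff (default V_small), which
suppresses the speckle characteristic of negative contrast.

All spherical structuring elements are discrete balls
{voxels with center distance ≤ r}, implemented through distance transforms
(exactly equivalent, much faster at large radii). Background clearing uses
26-connectivity (the common default for 3D border-clearing operations);
foreground objects use 18-connectivity. Beads touching the volume border
are flagged in the result and can be excluded from cohort statistics, since
their morphometrics are truncated by the field of view.

## Per-bead morphometrics

Each segmented bead is analysed as the binarized foreground restricted to
its watershed label (so pores reappear in the per-bead image I):

- **Pore decomposition.** I_conv is the discrete convex hull image (voxel
  centers inside the hull polytope of the bead's voxel centers); closed
  pores I_cl are background components of ¬I not connected to the crop
  border; I_fill = I ∨ I_cl; open pores I_op = I_conv ∧ ¬I_fill. Voxel
  counts then satisfy V_conv = V + V_op + V_cl *exactly, by construction* —
  asserted for every bead processed. Porosity is P = 1 − V/V_conv ∈ [0, 1).
- **Sizes.** Equivalent diameter (6V/π)^(1/3); principal axis lengths from
  the eigenvalues λ_k of the voxel-coordinate covariance with the per-voxel
  second-moment correction of 1/12 voxel² on the diagonal,
  L_k = 2·sqrt(5 λ_k) (the ellipsoid with the same normalized second
  central moments), sorted descending. For porous beads these are computed
  on the hull image (the enveloping particle); for non-porous beads on the
  bead image — both supports are available and the choice is recorded per
  variant.
- **Convex surface area** by Crofton's intercept-count formula over 13
  systematic directions (3 axes, 6 face diagonals, 4 body diagonals) with
  classical solid-angle weights. Digitized spheres are recovered within
  5 %; flat axis-aligned faces are the scheme's worst case (a cube lands
  ~7 % low in the continuous limit, ~13 % low at 10 voxels), which is an
  inherent anisotropy of the direction set, not a defect of this
  implementation.
- **Accessible surface area** from alpha shapes: the alpha complex of the
  bead's voxel centers keeps every Delaunay tetrahedron whose circumsphere
  radius is at most the probing radius, and the reported area is the
  triangulated boundary of the kept tetrahedra (zero-area slivers
  removed). The probing radius models the size of a cell feeling the
  surface: small probes enter pores and see more area, an infinite probe
  returns the convex hull area (cross-checked against the Crofton estimate
  on the hull image, agreeing within 10 %). Probing radii are given in
  voxels — the default sweep is [2, 3, 4, 10, 15, 20, 25, 38, 50, +∞] —
  and map to cell sizes in µm as radius × voxel size (100 µm for 50 voxels
  at 2 µm). Lattice point sets are maximally degenerate for Delaunay
  triangulation, so a deterministic ±1e-4-voxel jitter restores general
  position; its effect on areas is below 0.1 %.

## Cohort statistics

Boxplot-style summaries use the midpoint quantile convention (linear
interpolation of order statistics at probabilities (k − 0.5)/n) and the
1.5·IQR rule: values above q3 + 1.5(q3 − q1) or below q1 − 1.5(q3 − q1) are
outliers; whiskers are the extreme non-outlier values. Summaries always
carry true values — any clipping of extreme outliers is a display concern
only.

Swelling is the percent change of a central measure (median by default,
mean available) of a morphometric between the dry and wet cohorts.
Attachment surface area per gram dry weight is S̃/(Ṽ·d) for non-swelling
beads (S̃, Ṽ the median surface and volume, d the density in g/ml) and
S̃ × beads-per-gram for swelling beads, with the count either from the
manufacturer or estimated as imaged count / sample weight.

Cohorts are compared with the unpaired equal-variance Student's t-test:
validation cohorts generally have unequal sizes, which precludes pairing
(a paired variant is available for genuinely matched samples). Normality is
tested with a one-sample Kolmogorov–Smirnov test on z-scored data against
the standard normal — testing raw morphometrics against N(0, 1) directly
would reject on scale alone, so the z-scoring is a deliberate
interpretation. α = 0.05 throughout; no multiple-testing correction is
applied, matching common practice for these descriptive comparisons.

The validation harness compares any two labelings of one grid the same
way a manual-versus-automatic study would: per-bead records are pooled per
group (no bead matching), each morphometric row carries both groups'
mean/std/quartiles and the t-test, and the count discrepancy is reported as
100·(n_ref − n_test)/n_ref, rounded to integer percent for the headline.
For phantom studies a greedy one-to-one IoU matcher scores segmentations
against voxel ground truth.

## Synthetic phantoms

No raw CT volumes of commercial microcarrier samples are publicly
available, so validation rests on phantoms that emulate what matters to
the algorithms:

- beads inside a liquid-filled cylinder ("tube") surrounded by air, giving
  the two background phases and realistic container-wall edges;
- spheres, or randomized ellipsoids with axis ratios in [0.6, 1] (mimicking
  near-spherical gelatin carriers), optionally with interior spherical
  cavities (closed pores), cylindrical channels to the exterior (open
  pores, the channel radius being the pore-throat radius), or spherical
  surface dents (concave carriers);
- placement by rejection sampling (10 000 retries per bead, then a packing
  error naming the first unplaceable bead) with a configurable minimum gap
  and an optional fraction of deliberately touching pairs; each bead has
  its own RNG stream, so adding beads never perturbs earlier ones;
- 8-bit rendering at three configurable material gray levels plus clipped
  additive Gaussian noise. Defaults: 2 µm voxels, means (20, 100, 210),
  noise σ = 8 — peak separations ≥ 80 gray levels, comfortably above the
  3:1 separation-to-noise ratio at which the three-peak valley structure
  survives.

Ground truth records per-voxel labels, exact centers/radii/semi-axes, and
per-bead volumes with closed/open pore counts classified by
connected-component analysis against the background (channels may
legitimately convert a cavity they intersect into open pore space; the
truth reflects the realized geometry, not the carving intent). Cavities
shrink to fit small beads and channels start off-center so interior
cavities usually survive.

What the phantoms do *not* model: CT reconstruction artifacts (beam
hardening, rings, partial-volume blur beyond voxelization), polychromatic
attenuation, intensity gradients from imperfect stain diffusion, and truly
irregular (non-ellipsoidal) bead shapes. Passing phantom benchmarks
therefore demonstrates the correctness of the geometry and statistics under
the stated imaging model, not robustness to every artifact of real
acquisitions.

## Benchmark conditions and measured behaviour

The canonical benchmarks (`beadct.benchmarks`, shared by the test-suite and
`scripts/acceptance.py`) use 256³ grids at 2 µm voxels:

- *Sphere benchmark*: 5 spheres, radii 20–40 µm, ≥ 4 µm gaps; Hough sweep
  16–44 µm. Expected: all beads found, centers within 2 voxels, radii
  within 1 voxel, model volumes within 5 % of voxel counts.
- *Porous benchmark*: 50 porous ellipsoids, radii 28–44 µm, two cavities
  (6–10 µm) and two channels (throat 3–5 µm) each, 10 % touching pairs.
  Segmentation with V_small = 4000 µm³, R_p = 6 µm (above every throat
  radius, so all open pores seal), R_op = 4 µm, watershed σ = 6 voxels
  (sized to the 14–22-voxel bead radii). Expected: label count within
  ±10 % of truth, ≥ 90 % of beads matched one-to-one at IoU ≥ 0.5,
  porosity recovered within 0.05 absolute on matched beads, alpha-shape
  area at infinite probing radius within 10 % of the Crofton hull area.
- *Conservation sweep*: four 50-bead packs of smaller porous beads; the
  pore-decomposition identity must hold exactly for every bead.
- *Statistics*: the outlier rule must match a brute-force filter on 1000
  random vectors; the t-test type-I error over 1000 null simulations
  (n = 50 per group) must lie in [0.03, 0.07]; KS must pass a normal and
  flag a lognormal sample; digitized-solid sanity checks (ellipsoid axes
  within 3 %, sphere equivalent diameters within 1 voxel).

Problem sizes were chosen once as the smallest grids at which all beads are
well resolved (bead radii ≥ 14 voxels) while a full run stays comfortable
on a single CPU; they are the package's study conditions, not tuned
quantities.

## Known limitations

- The watershed tends to oversplit elongated beads and undersplit deeply
  overlapping pairs; the benchmark's ~10 % count error budget reflects
  this.
- Porosity metrics are the most sensitive to segmentation errors: a split
  bead acquires artificial concavity and hence inflated open-pore volume.
- The Crofton estimator's flat-face bias (above) matters for cuboid
  objects, not for the rounded shapes of real carriers.
- Only isotropic voxels and 8/16-bit TIFF stacks are supported; DICOM and
  proprietary scanner formats are out of scope, as are GPU execution and
  interactive watershed editing.
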