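# Methods

`pelvamp` re-implements the computational core of an MRI reading-support
pipeline for deep endometriosis (DE): multi-organ pelvic segmentation
losses, lesion morphometry, shape-radiomics adhesion classification, and the
evaluation statistics used in reader studies.  Because no patient MRI can be
shipped, the package is organized around a synthetic phantom generator with
analytically known ground truth; every downstream stage is validated against
that truth.

## Imaging model and grids

All volumes live on an anisotropic grid of 0.6 × 0.6 mm in-plane and 6.0 mm
through-plane spacing, the resolution the clinical pipeline resamples both
sequences to.  Axis convention: axis 0 = in-plane rows (anterior→posterior
in the phantom), axis 1 = in-plane columns, axis 2 = slice (through-plane).
Preprocessing consists of per-volume z-score normalization (degenerate
constant volumes are rejected), physical-extent-preserving resampling
(linear for intensities, nearest-neighbour for masks; voxels are treated as
cells, so an N-voxel axis of spacing s maps to round(N·s/t) voxels of
spacing t), and a four-step training augmentation: random zoom in
(0.9, 1.2), a random monotone intensity warp, an additive offset drawn from
(−0.1, 0.1) of the image SD, and Gaussian noise N(0, 0.1).  The intensity
warp is a random monotone piecewise-cubic (PCHIP) map of the normalized
intensity range; monotonicity preserves intensity ordering, which is the
property segmentation targets rely on.  Whole-volume inference uses
sliding-window tiling (default patch 384 × 384 × 24 voxels, overlap 0.5)
with uniform averaging of overlapping patch predictions; whether the
original system averaged uniformly or with distance weights is not
documented, and uniform weights keep the stitched output of any voxel-wise
predictor exactly equal to its whole-volume application — a property the
tests exploit.

## Phantoms

Each phantom sample contains a sagittal "T2-like" stack with uterus,
bladder, rectum, two ovaries and an optional plaque, and an axial "T1-like"
stack with an optional ovarian endometriotic cyst (OEC).  All organs are
ellipsoids (the rectum an elongated tube) placed by fixed fractions of the
grid's physical extent with small random jitter, so the same layout logic
scales from desk-size 64 × 64 × 12 grids to the default 128 × 128 × 16.
Tissue mean intensities (uterus 0.60, bladder 0.90, rectum 0.45, ovary 0.70,
plaque 0.35, T2 background 0.12; cyst 0.85 on T1) are package conventions on
a 0–1 scale — chosen to mimic T2/T1 contrast qualitatively (urine bright on
T2, blood products bright on T1, fibrotic plaque dark) — plus Gaussian noise
(default SD 0.05).

**Plaque.** The posterior uterine surface is locally flattened (the uterine
ellipsoid is truncated by a plane at 0.75 of its anterior-posterior
semi-axis) and the plaque is a band of constant thickness grown outward from
that face, slice by slice, using the in-plane Euclidean distance transform.
A flat contact face was chosen because the depth measurement (below)
constructs a chord through the contact set; on a strongly curved arc the
chord-to-apex sagitta (~1–2 mm at uterine curvature) would contaminate the
measured depth, whereas on a flat face the requested depth is recovered
exactly up to half an in-plane voxel.  Pixels are included when their center
lies within the band extended by half a pixel, so any nonzero depth keeps at
least one pixel ring and the rasterized thickness is the rounded voxel count.

**Cysts.** The cyst is an ellipsoid with the requested in-plane major/minor
axes, rotated by a random in-plane angle, centered exactly on a slice plane
so the largest cross-section is the analytic mid-slice.  The through-plane
semi-axis tracks the minor axis (cysts are modelled roughly prolate), so
scaling all axes by f^(1/3) scales volume by f — used by the pre/post
surgery pairs, which shrink cyst volume by a per-sample random factor in
[0.1, 0.9].

**Adhesions.** Seven locations (left ovary–rectum, right ovary–rectum,
left–right ovary, uterus–left ovary, uterus–right ovary, uterus–rectum,
uterus–bladder) carry per-patient Bernoulli labels with default prevalences
(0.38, 0.37, 0.16, 0.73, 0.66, 0.62, 0.06) matching the positive fractions
of the clinical cohort the pipeline was built for.  A flagged pair is
deformed in two ways: (1) both organs are stretched by a factor 1.18 along
the line joining their centers (a direction-coded shape signal — the axis
diameters and elongation/flatness of the 14-feature set are axis-sensitive,
which lets a classifier distinguish which neighbour an organ deforms
toward); and (2) the inter-organ gap is bridged by assigning the free-space
corridor (voxels where the sum of distances to the two organs is within
3 mm of the minimal gap) to the nearer organ, which brings the pair into
contact and flattens both surfaces locally, lowering sphericity.  Where a
stretched pair overlaps, contested voxels go to the organ with the smaller
normalized ellipsoid coordinate, again producing a flat interface.  The
bridge keeps a 2-pixel margin around the plaque band so the plaque–uterus
contact surface stays intact.  Deformation magnitudes were fixed once at
generator-design time; the recovery tests then ask whether the pipeline can
detect them, not the other way round.

Phantom geometry is validated at generation: organs must not clip the grid,
unflagged organ pairs must not overlap, and a plaque that no longer fits
raises a geometry error.

## Plaque depth and severity

Depth is measured per sagittal slice: (1) the plaque contour (8-connected
boundary pixels) is intersected with the set of pixels within a
predetermined contact distance (default 1.2 mm = 2 in-plane voxels) of the
uterus; (2) a line parallel to the contact surface is estimated from the
contact set; (3) the two lines parallel to it that enclose all plaque pixels
are found; (4) depth = the distance between these supporting lines.  The
reported depth is the maximum over slices, and the width is the plaque
extent parallel to the bounding lines on that slice.  Severity is graded
none (0 mm), mild (< 5 mm), severe (≥ 5 mm); exactly 5 mm grades severe.

Two numerical choices matter.  First, the chord direction is the principal
(total-least-squares) direction of the contact set rather than the chord
through its two most distant points: at the default contact distance the
contact set is two pixel rows thick, and the extreme-point chord always
picks a diagonal across the set, biasing depth upward by about one pixel;
the principal direction is the stable estimate of a line parallel to the
contact surface.  Second, the supporting lines bound pixel *areas*, not
centers: one in-plane pixel of support is added to the projected center
span, so an axis-aligned k-pixel slab measures exactly k pixel widths.  (The
full footprint projection |n₀|s₀+|n₁|s₁ would systematically overshoot
oblique bands.)

## Cyst axes and volumes

Each lesion (26-connected 3D component, largest first) is fitted on every
axial slice by a direct least-squares ellipse fit (Halir–Flusser, via
scikit-image) of the subpixel half-level contour; the slice whose fitted
ellipse has the largest area is reported, with full axis lengths in mm.
Fits need at least 5 foreground pixels and fail explicitly on degenerate
contours.  Volumes are voxel counts times the voxel volume (2.16 mm³ at the
default spacing); volume change is post minus pre.

## Segmentation losses and backbone

The training objective is focal loss plus soft-Dice in a 1:1 ratio; γ = 2 by
default (the focal-loss literature's standard value — the source recipe
cites the focal loss without stating γ).  Soft-Dice is averaged over
foreground classes with an ε that keeps classes absent from both prediction
and target neutral.  The optional boundary term (used for the cyst model)
follows the signed-distance formulation: the mean over voxels of predicted
foreground probability times the signed distance in mm to the true boundary
(negative inside), averaged over foreground classes; an empty target defines
the term as 0 with a warning.  The boundary weight relative to focal+Dice is
1.0 and configurable; the original weighting is not documented.

The demonstration backbone is deliberately small and explicitly pluggable: a
voxel-wise softmax classifier over fixed multi-scale features (intensity,
two Gaussian scales, gradient magnitude, normalized coordinates), trained by
per-volume Adam steps on the combined loss with fully analytic gradients
(focal and Dice gradients are chained through the softmax Jacobian; the
gradient is finite-difference checked in the tests).  Anything exposing
`predict_proba(volume) -> (C, *shape)` and a `classes` tuple plugs into
ensembling, sliding-window inference and evaluation.  Ensembles average
member probabilities voxel-wise (members differ only by initialization
seed); the argmax of the ensemble mean is the final mask.

## Shape radiomics

The 14 descriptors per organ follow the standard shape-3D radiomics
definitions: elongation √(λ₂/λ₁) and flatness √(λ₃/λ₁) plus the three axis
lengths 4√λ from the eigenvalues of the physical voxel-center covariance;
mesh surface area and divergence-theorem volume of the half-level
marching-cubes isosurface; voxel-count volume; sphericity (36πV²)^⅓/A; the
maximum pairwise boundary-voxel distances in 3D and within each orthogonal
plane family; and the surface-to-volume ratio.  The binary indicator is
smoothed by a 0.8 mm Gaussian before meshing: the raw half-level isosurface
of a binary mask is a voxel staircase that overestimates a sphere's area by
~8%, while the smoothed isosurface recovers it within ~1% (masks too small
to survive smoothing fall back to the raw indicator; a single voxel then
meshes to the octahedron through its face midpoints).  The 56-dimensional
image vector concatenates the 14 features over uterus, bladder, rectum and
the merged left+right ovary, in fixed order with stable `organ__feature`
column names.  A missing organ yields NaNs plus a missingness flag;
dataset assembly imputes column medians.

Note on conventions: smaller elongation/flatness means more rod- or
plate-like (a rod's elongation tends to 0); a strictly one-voxel-wide line
has a singular covariance and is rejected as degenerate.

## Adhesion classification

One LightGBM binary classifier per location (7 independent models, not
multi-label), 200 trees of depth ≤ 4 at learning rate 0.1 with deterministic
single-threaded training — small-data-safe defaults, as no hyperparameters
are documented for the original.  Evaluation is patient-grouped stratified
5-fold cross-validation (all images of a patient share a fold; folds
approximately preserve the positive fraction, falling back to grouped-only
with a warning when stratification is unsatisfiable).  Recall, precision and
F1 are computed from the pooled out-of-fold predictions at a 0.5 probability
threshold, with 95% percentile-bootstrap confidence intervals (2000
resamples) over the pooled prediction pairs; undefined cells (no positives,
or no predicted positives) are reported as 0 with explicit flags.  A
permutation null re-runs the full CV with patient-level label shuffling;
its F1 distribution centers at the prevalence-consistent chance level.

## Detection and agreement metrics

Plaque localization uses per-component tight bounding boxes (26-connected,
half-open voxel coordinates) and greedy confidence-ordered matching: each
prediction claims the unmatched truth box of highest IoU if IoU ≥ 0.01 — the
permissive threshold appropriate for small, irregular lesions where any
meaningful localization counts ("exceeded 0.01" is implemented as ≥ 0.01).
Average precision is the all-point interpolated area under the
confidence-ranked precision-recall curve pooled over images; with one lesion
class it equals mAP, and operating points (recall, precision) can be read at
any confidence cut.  Dice similarity defines the both-empty case as 1 with a
flag, excluded from mean-DSC summaries.  Reader sensitivity is TP/(TP+FN)
per reader against a truth table, undefined (NaN, flagged) when no positives
exist; Cohen's kappa is unweighted — for severity the three grades form an
unordered ternary scale — and defined as 1 with a flag when both raters are
constant and identical.  Pearson correlation requires n ≥ 3 and nonzero
variance.

## What the phantoms do and do not show

The phantom generator produces geometric organs with piecewise-constant
intensities, Gaussian noise and deterministic deformation — no MR physics,
bias fields, peristaltic motion, anatomical variability beyond size/position
jitter, or ambiguous lesion boundaries.  Passing the recovery gates
therefore demonstrates that the *measurement and learning machinery* is
correct (geometry is recovered to voxel precision, synthetic effects are
detected, metrics match their oracles); it does not predict clinical
performance on patient MRI, where annotation ambiguity and contrast
variability dominate.  Consistent with that, the toy segmenter reproduces
the qualitative difficulty ordering of the real task — large smooth organs
segment well while the thin plaque class lags — without approaching the
original system's architecture or scale.

## Problem sizes and defaults

Default grids are 128 × 128 × 16 (T2) and 96 × 96 × 12 (T1); recovery
studies use 200 phantoms; the end-to-end demo uses 50 phantoms on
64 × 64 × 12 grids with 30 training epochs — sizes chosen so the full suite
and the reproduction script each run in minutes on a single CPU while
keeping every estimate comfortably inside its statistical gate.  All
randomness flows from explicit integer seeds; cohorts, training and CV are
bit-reproducible for a fixed seed.

## Known limitations

* Plaques are modelled only on the posterior uterine surface with a locally
  flat contact face; strongly curved contact surfaces would re-introduce a
  chord-sagitta bias that the measurement does not correct.
* Through-plane quantization at 6 mm slices dominates cyst-volume error for
  small cysts; volume-change ratios are accurate to ~5% only for cysts
  spanning several slices.
* The adhesion effect size in the phantoms is a design choice; real
  adhesion-induced deformation is subtler and confounded across locations.
* The numpy softmax backbone has no spatial receptive field beyond its
  fixed feature scales; it is a stand-in for demonstrating the training
  contract, not a segmentation architecture.
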