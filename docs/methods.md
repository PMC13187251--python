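# Methods

## Problem and model

A stack of k whole-mount histology sections, cut at a slice interval of
hundreds to thousands of µm, is to be recomposed into a 3-D volume. Each
section carries an unknown rigid pose (rotation anywhere in 0–360°,
translation) from mounting, plus staining variation. Because the interval
far exceeds the size of fine structures, adjacent sections share coarse
anatomy but not fine landmarks; the alignment signal must therefore come
from global tissue architecture. The per-slide transform is modelled as a
pure rotation + translation about an explicit center — determinant 1, both
singular values 1, asserted on every estimate. Scale and shear are excluded
by design: true cross-section size differences between adjacent sections
(strongest near the specimen ends) are anatomy, not error, and a scale fit
would "correct" them away. Horizontal mirror flips are assumed corrected
upstream and are never generated or searched for.

## Pipeline stages and parameters

**Preprocessing.** Tissue masks come from Otsu's threshold on the 8-bit
luminance (exactly the exhaustive between-class-variance maximizer over the
256 possible splits; first maximum on ties), tissue being the dark class.
Cleanup is morphological closing then opening with a 2 px disk at
processing resolution, then removal of connected components below 0.1% of
the foreground area; a constant-intensity image yields an all-background
mask flagged degenerate. Background is replaced by white (glass). Stain
normalization is Reinhard's channel-statistics mapping in Ruderman's lαβ
space, computed over foreground pixels only (background would bias the
means); the target is the element-wise median of the per-slide (mean, std)
triples, a robust center for the stack. Slides with zero foreground
variance pass through unchanged with a warning. One spacing serves the
whole stack: the candidate (pyramid ladder ∪ integer multiples of the
level-0 spacing) that brings the largest slide's longer side closest to
`target_pixels` = 2000; ties go to the coarser spacing. All slides are then
padded, centered, onto a square canvas sized by the largest resampled
extent; pad offsets and scales are recorded so estimated transforms compose
exactly back to each slide's level-0 frame.

**Initialization and flips.** The enclosing ellipse of each mask (centroid
and second-order moments; for a filled ellipse these recover the generating
parameters exactly) defines center and orientation. The reference is the
middle slide, lower middle for even k. Orientation matching is mod 180°
with the rotation delta wrapped to (−90°, 90°]; an ellipse with axis ratio
below 1.05 is flagged degenerate and falls back to centroid-only alignment.
The remaining half-turn ambiguity is resolved outward from the reference:
each slide keeps whichever of {pose, pose+180°} has the higher cosine
similarity between flattened global-feature grids against its
already-resolved neighbor; ties (difference < 1e-6) keep the unflipped
pose, and the reference is never flipped. Flattened (token-order-sensitive)
aggregation is essential here — mean-pooled tokens would be rotation-blind.
Flip-test features are extracted at 252 px with 7 px tokens (a 36×36
grid): this keeps a small end-section covered by enough tokens to make the
flipped/unflipped contrast decisive, and avoids pointless upsampling of the ~256 px processed
frames. Background tokens (near-white, featureless) are
zeroed before the comparison so empty glass cannot dominate the cosine.

**Dense matching (classical backend).** Per-cell descriptors on an 8 px
grid — mean RGB (3), luminance standard deviation (1), 8-bin
gradient-orientation histogram (8), L2-normalized, d = 12 — matched by
mutual nearest neighbor under cosine similarity (floor 0.9). Because
matching always runs on views already posed by the previous stages,
candidates are restricted to a 32 px spatial window; this suppresses the
arbitrary correspondences that featureless tissue interior would otherwise
produce, at the cost of capping the residual motion matches can express
(ample after initialization). Matched coordinates are refined to subpixel
precision by phase correlation on 24 px windows. The oracle backend
replaces all of this with exact planted correspondences (configurable
outlier fraction and noise) derived from the known per-slide transforms;
its global descriptors delegate to the classical routine so the full
pipeline, including flip resolution, runs under it.

**RANSAC rigid estimation.** 1000 iterations of 2-point samples; each
sample gives a closed-form rigid candidate; matches within 3 px (processing
resolution) are its consensus. The best consensus is refined by
least-squares (rotation from the SVD of the cross-covariance with the
reflection branch rejected, translation from centroids), inliers are
recomputed, and the refinement repeated once. A consensus must contain at
least 3 matches, at least 6 when that many candidates exist, and at least
10% of all candidates: a 2-point model plus a handful of coincidences can
always "explain" 3–5 matches, and near the specimen ends the genuine
residual field is radial (cross-section shrinkage) which no rigid model
fits — in both situations the caller's current pose is more trustworthy
than the spurious fit, so the estimator refuses and the pair falls back to
its initialization pose, recorded in the per-pair diagnostics.

**Stack alignment** proceeds outward from the reference on both sides,
each slide matched against its already-aligned neighbor as currently
posed; the estimated residual composes onto the slide's pose. Per-pair
error does not rebound: an error ε per pair bounds the end slide by
ε·(k−1), which the tests verify on oracle phantoms.

**Deformable refinement** (optional, off by default, intended for densely
sampled stacks): a thin-plate-spline fitted from the inlier matches with
regularization 1e-3, then *resampled onto a Cartesian control grid*
(spacing 32 px) whose exact interpolant is stored. The grid form is what
makes the field linearly rescalable: scaling node coordinates and
recomputing the interpolation weights is equivalent to scaling the warp
(TPS is equivariant under similarity transforms of domain and range), so no
refit against the matches is needed at other resolution levels. The TPS
solver (r²·log r kernel plus affine part) is written in-module because the
rescaling contract and the bit-stable evaluation order of the tiled warp
depend on it; scipy's thin-plate RBFInterpolator serves as the independent
cross-check in the tests. Fewer than 4 non-collinear inliers refuse
refinement and return the identity field.

**Warping** uses backward (pull) maps throughout: each output pixel stores
the source coordinate to sample, computed from its absolute output index,
so the map restricted to a tile equals the global map on that tile and
tiled output is bit-identical to a monolithic warp at any tile size.
Interpolation is bilinear for images, nearest for masks; out-of-source
samples take the configured background color. Streamed writes hold one
tile at a time (the stream wrapper counts live tiles; reduced pyramid
levels are built one level at a time afterwards). The 3-D rendering
interpolates adjacent registered masks through-plane (linear cross-fade,
binarized at 0.5 — the midpoint is the only symmetric choice).

## Metrics

Orientation deviations are computed on the circle and re-expressed relative
to the reference slide (whose deviation is identically 0); a case passes at
threshold 15°. Overlap divides each adjacent-pair intersection by the
*smaller* mask's area and averages the k−1 pairs; an empty mask makes its
pair 0 and flags it. TRE is the mean over pairs of the per-pair *median*
match distance (median for robustness to outlier matches), reported in px
and mm via the processing spacing. The estimated TRE re-runs dense matching
plus RANSAC inlier selection on the registered rasters without applying
any transform; a pair whose matches admit no rigid consensus still
contributes its unfiltered median (the misalignment is real, only the
inlier filter is unavailable), while a pair with under 3 matches is
skipped and flagged.

## Synthetic phantoms

The generator emulates exactly the premise the method rests on. A smoothly
bending superellipsoid organ (96×256×256 voxels; 40 µm in-plane, 400 µm
through-plane — anisotropic because section thickness dwarfs pixel spacing)
carries two structure populations: coarse blobs whose z-diameter exceeds
the 4000 µm slice interval (they persist between adjacent sections — mean
footprint IoU > 0.5 where present in both) and fine blobs thinner than the
interval (essentially never shared between sections, IoU ≈ 0). Sections are
cut every 10th z-voxel (10 slides by default, seconds to generate), then
independently perturbed: rotation uniform in 0–360° about the slide center,
translation up to ±15 px, optional planted 180° flips, channel-wise affine
stain jitter (±5%). Three fiducial rods pierce every section and provide
exact landmarks, in the manner of laser-drilled calibration holes in
serially sectioned specimens. Asymmetry is guaranteed twice over — an
off-center coarse structure and a darkened 70° angular sector around the
(drifting) organ center — because 180° flip detection is undecidable on a
point-symmetric section; the sector construction matters for the small end
sections that planted blobs can miss. The ground-truth record stores every
planted transform and transformed landmark, so recovery error is measured
exactly.

What the phantom does not emulate: nuclei-level texture, stain chemistry,
tissue folding/tearing, scanner artifacts, and missing or damaged sections.
Passing tests therefore demonstrate the geometry and the estimation
machinery — initialization, flip logic, robust rigid estimation, error
propagation, metric formulas, resolution scaling — not descriptor quality
on real histology; on real WSIs the classical backend is a baseline and
the pluggable pretrained backend (ViT token grids + a learned dense
matcher) is the intended production feature source.

## Problem sizes used in the shipped experiments

Reconstruction experiments use the default 10-slide phantom at 256 px
processing resolution; parameter-recovery sweeps use 20 phantom seeds, flip
sweeps 20 perturbation seeds of one volume, and the slice-distance
experiment slices one volume per seed at 2000 µm and keeps every n-th
section for n = 1…5 (5 seeds), reconstructing each subsampled stack with
the classical backend. These sizes make the entire suite run in minutes on
one CPU while leaving every qualitative contrast (flip margins, consensus
fractions, the sparsity trend) far from threshold.

## Numerical choices and degenerate inputs

Angles are degrees in (−180°, 180°] (mod-180 wrapping to (−90°, 90°] during
initialization); rotation matrices are built from the angle so rigidity is
exact by construction. Bilinear sampling rounds half away from zero into
uint8. RANSAC, the oracle backend, perturbations, and per-stage seeds all
derive from explicit integer seeds (one global seed expands through a seed
sequence), making alignment JSON byte-reproducible. Degenerate cases are
defined, not exceptional: constant images give flagged all-background
masks; zero-variance slides skip stain normalization; near-circular
ellipses fall back to centroid alignment; empty masks zero-and-flag their
overlap pair; insufficient matches or no consensus keep the current pose
and are logged.

## Known limitations

Pairwise chaining accumulates error linearly with distance from the
reference (bounded, but not jointly optimized); there is no global bundle
adjustment. The overlap metric saturates for nested masks and cannot
detect in-plane rotation error of a round specimen on its own — no single
metric captures reconstruction success, which is why three are reported.
The estimated TRE conflates residual misregistration with true anatomical
change across the interval; on the phantoms this floor is visible as
~0.5 mm at the default 4 mm interval even when fiducials align to a few
pixels. The classical backend's spatial search window assumes
initialization has already removed large pose errors; it is not a
general-purpose wide-baseline matcher.
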