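# histostack

Three-dimensional reconstruction of sparsely sampled whole-mount histology
section stacks.

Whole-mount prostatectomy (and similar) specimens are sectioned at intervals
of several millimetres, each section digitized as a gigapixel whole-slide
image (WSI) with an arbitrary rotation and placement on the glass. At such
sampling intervals adjacent sections no longer share fine landmarks — small
glands and lesion outlines appear and disappear between slides — but their
coarse tissue architecture persists. `histostack` reconstructs the 3-D
specimen by aligning *global* features (patch-grid descriptors of the tissue
layout) rather than local keypoints, deliberately restricting every
per-slide transform to a rotation plus translation: scale and shear
"corrections" would erase anatomically real size differences between
adjacent sections.

## Method

For a stack of *k* sections the pipeline runs:

1. **Preprocessing** — Otsu tissue masking with morphological cleanup,
   background set to white, Reinhard-style stain normalization in the lαβ
   color space toward the element-wise **median** of the per-slide channel
   statistics, resampling to one common spacing (chosen so the largest
   slide lands closest to 2000×2000 px), padding to a shared square canvas.
   RGB is preserved throughout.
2. **Initialization** — an enclosing ellipse (image moments) gives each
   section a center and orientation; all sections are mapped onto the
   middle slide *r* = ⌊(k−1)/2⌋. Ellipse orientation is defined only
   mod 180°, so a half-turn ambiguity remains.
3. **Flip resolution** — iterating outward from the reference, a section is
   rotated by 180° exactly when that raises the cosine similarity of its
   global feature grid with its already-resolved neighbor.
4. **Rigid finetuning** — outward iterative pairwise alignment
   (*r*+1 → *r*, then *r*+2 → aligned *r*+1, symmetrically on both sides):
   dense feature matches feed a RANSAC estimator (2-point samples,
   closed-form rigid candidates, least-squares refinement over the
   consensus), and the residual composes onto the current pose.
5. **Optional thin-plate-spline refinement** — off by default; a backward
   TPS field on a Cartesian control grid, for densely sampled stacks.
6. **Full-resolution propagation** — rigid parameters scale linearly with
   resolution and the TPS control grid rescales without refitting, so the
   alignment estimated on ~2000 px images applies to the gigapixel
   originals; warping streams backward-mapped tiles (each output pixel
   stores its source coordinate independently, so tiling introduces no
   boundary artifacts) into a tiled pyramidal TIFF at bounded memory.

Reconstruction quality is scored by three complementary metrics: the
**orientation accuracy** (a case passes when every slide deviates ≤ 15°
from its ground-truth rotation relative to the reference), the adjacent-pair
**overlap** O = 1/(k−1) · Σₙ |Aₙ ∩ Aₙ₊₁| / min(|Aₙ|, |Aₙ₊₁|) (the smaller
section is the denominator because real size differences must not be
penalized), and the **target registration error**
TRE = 1/(k−1) · Σₙ median᛫ᵢ‖Fₙ,ᵢ − Fₙ₊₁,ᵢ‖ over matched feature pairs,
reported in pixels and mm. The estimated TRE re-detects matches on an
already-registered stack — including stacks registered by other tools —
without modifying any transform.

Three feature backends implement one contract: `oracle` (planted
ground-truth correspondences, for validation), `classical` (deterministic
weight-free per-cell descriptors: mean RGB, luminance spread, gradient
histogram), and `pretrained` (a plug-in contract for a ViT token-grid
extractor + learned dense matcher; requires torch and weights, everything
else runs without it).

A synthetic phantom generator produces organ-like volumes whose coarse
structures outlast the slice interval while fine structures decorrelate
between sections, with fiducial rods for landmark TRE and exact per-slide
ground-truth transforms — so the whole pipeline is testable without any
external data or pretrained models.

## Worked example

```python
from histostack import make_phantom_stack, reconstruct, PipelineConfig, ClassicalBackend

stack, gt, spec = make_phantom_stack(seed=7)   # 10 sections, planted 0-360° rotations
res = reconstruct(stack, PipelineConfig(), seed=7, backend=ClassicalBackend(), gt=gt)
print(res.reports["orientation"]["deviations_deg"])
print(res.reports["overlap"]["mean_overlap"])
print(res.reports["estimated_tre"]["tre_px"])
```

prints (rounded):

```
orientation deviations (deg): [0.19, -0.12, -0.07, 0.02, 0.0, -0.22, -0.04, -0.06, -0.09, -0.08]
case accurate (15 deg): True
mean overlap: 0.9993
estimated TRE: 13.06 px = 0.522 mm
fiducial TRE: 5.56 px
```

Every planted rotation (uniform in 0–360°, including the 180° ambiguities
the ellipse cannot see) is recovered to within a quarter degree; adjacent
registered sections overlap almost completely; the estimated TRE of ~13 px
(0.5 mm at 40 µm/px) reflects genuine anatomical change across the 4 mm
slice interval, not misregistration — the fiducial rods, which exist in
every section, land within 6 px.

The same pipeline is available from the shell:

```bash
histostack synth --seed 7 --out phantom/          # stack + ground truth + landmarks
histostack reconstruct phantom/ --out recon/      # alignment.json, reports, registered TIFFs
histostack evaluate recon/ --spacing 40           # read-only scoring
histostack render3d recon/ --out volume.tif       # through-plane interpolated 3-D mask
```

## Documentation

`docs/methods.md` describes the model, the parameter choices and their
rationale, what the phantom generator does and does not emulate, and the
package's known limitations.
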