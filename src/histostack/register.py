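"""Per-slide transform estimation: the reconstruction itself.

Stages, in pipeline order:

1. **Initialization** — an enclosing ellipse is fitted through each tissue
   mask (centroid + second-order image moments); every slide is mapped so
   its ellipse center and major-axis orientation coincide with those of the
   reference slide (the middle of the stack). Ellipse orientation is only
   defined mod 180°, so a 180° ambiguity remains.
2. **Flip resolution** — iterating outward from the reference, each slide
   keeps whichever of {current pose, current pose + 180°} gives the higher
   cosine similarity of global features against its already-resolved
   neighbor.
3. **Finetuning** — outward iterative pairwise alignment: dense matches
   between each slide (as currently posed) and its already-aligned neighbor
   feed a RANSAC rigid estimator; the consensus refinement composes onto the
   initialization pose. The transform is deliberately restricted to
   rotation + translation — no scale or shear — because true size
   differences between adjacent sections are anatomically plausible and must
   not be "corrected".
4. **Optional TPS refinement** — a thin-plate-spline field fitted from the
   inlier correspondences, stored on a Cartesian control grid so it rescales
   linearly to any resolution level. Off by default; meant for densely
   sampled stacks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .features import (
    FeatureBackend,
    InsufficientMatchesError,
    MatchSet,
    SlideView,
    cosine_similarity,
    dense_match,
    extract_global_features,
)
from .preprocess import ProcessedStack, TissueMask
from .transform import (  # noqa: F401  (re-exported types)
    DeformationField,
    RigidTransform2D,
    tps_fit,
    warp_image,
    wrap_angle,
)


class NoConsensusError(RuntimeError):
    """RANSAC found no consensus of at least 3 matches."""


# ---------------------------------------------------------------------------
# Ellipse pose
# ---------------------------------------------------------------------------


@dataclass
class EllipsePose:
    """Enclosing-ellipse summary of a tissue mask.

    ``angle`` is the major-axis orientation in degrees mod 180 (x axis
    rightward, y axis downward). ``degenerate`` marks nearly isotropic masks
    (axis ratio < threshold) whose orientation is unreliable.
    """

    center: tuple[float, float]
    angle: float  # [0, 180)
    axes: tuple[float, float]  # (major, minor) semi-axis lengths
    degenerate: bool = False


def fit_enclosing_ellipse(mask: TissueMask | np.ndarray, degenerate_ratio: float = 1.05) -> EllipsePose:
    """Fit an ellipse to a foreground mask via second-order image moments.

    For a filled ellipse the moment-derived center, orientation, and axes
    recover the generating parameters; for general tissue shapes they give
    the equivalent-ellipse pose used to initialize the alignment.
    """
    m = mask.mask if isinstance(mask, TissueMask) else np.asarray(mask) > 0
    ys, xs = np.nonzero(m)
    if len(xs) == 0:
        raise ValueError("empty mask")
    cx, cy = xs.mean(), ys.mean()
    dx, dy = xs - cx, ys - cy
    mxx, myy, mxy = (dx * dx).mean(), (dy * dy).mean(), (dx * dy).mean()
    angle = np.rad2deg(0.5 * np.arctan2(2 * mxy, mxx - myy)) % 180.0
    common = np.sqrt(max((mxx - myy) ** 2 + 4 * mxy**2, 0.0))
    lam1 = (mxx + myy + common) / 2.0
    lam2 = (mxx + myy - common) / 2.0
    major, minor = 2.0 * np.sqrt(max(lam1, 1e-12)), 2.0 * np.sqrt(max(lam2, 1e-12))
    return EllipsePose(
        center=(float(cx), float(cy)),
        angle=float(angle),
        axes=(float(major), float(minor)),
        degenerate=bool(major / minor < degenerate_ratio),
    )


# ---------------------------------------------------------------------------
# Stack alignment state
# ---------------------------------------------------------------------------


@dataclass
class StackAlignment:
    """Per-slide composed transforms into the reference slide's frame."""

    reference_index: int
    transforms: list[RigidTransform2D]
    flips_applied: list[bool] = None
    deformable: list[DeformationField | None] = None
    degenerate_init: list[bool] = None
    pair_diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        k = len(self.transforms)
        if self.flips_applied is None:
            self.flips_applied = [False] * k
        if self.deformable is None:
            self.deformable = [None] * k
        if self.degenerate_init is None:
            self.degenerate_init = [False] * k
        if not self.transforms[self.reference_index].is_identity(tol=1e-6):
            raise ValueError("reference slide transform must be identity")

    @property
    def k(self) -> int:
        return len(self.transforms)

    def to_dict(self, level0_spacing: float | None = None) -> dict:
        return {
            "reference_index": self.reference_index,
            "slides": [
                {
                    **t.to_dict(),
                    "flip": bool(f),
                    "level0_spacing": level0_spacing,
                    "deformable": d.to_dict() if d is not None else None,
                }
                for t, f, d in zip(self.transforms, self.flips_applied, self.deformable)
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StackAlignment":
        slides = d["slides"]
        return cls(
            reference_index=d["reference_index"],
            transforms=[RigidTransform2D.from_dict(s) for s in slides],
            flips_applied=[s.get("flip", False) for s in slides],
            deformable=[
                DeformationField.from_dict(s["deformable"]) if s.get("deformable") else None
                for s in slides
            ],
        )


def reference_index(k: int) -> int:
    """Middle slide; lower middle for even stack sizes."""
    return (k - 1) // 2


def initialize_stack(pstack: ProcessedStack) -> StackAlignment:
    """Ellipse-based rigid initialization to the middle-slide frame.

    Each slide is rotated so its major axis matches the reference's (mod
    180°, leaving the flip ambiguity) about its own ellipse center, then
    translated so the centers coincide. A degenerate (near-circular) ellipse
    falls back to centroid-only alignment for that slide.
    """
    poses = [fit_enclosing_ellipse(m) for m in pstack.masks]
    r = reference_index(pstack.k)
    ref = poses[r]
    transforms, degen = [], []
    for i, pose in enumerate(poses):
        if i == r:
            transforms.append(RigidTransform2D())
            degen.append(pose.degenerate)
            continue
        if pose.degenerate or ref.degenerate:
            delta = 0.0
        else:
            delta = wrap_angle(ref.angle - pose.angle, period=180.0)
        t = RigidTransform2D(
            theta=delta,
            tx=ref.center[0] - pose.center[0],
            ty=ref.center[1] - pose.center[1],
            center=pose.center,
        )
        transforms.append(t)
        degen.append(pose.degenerate)
    return StackAlignment(reference_index=r, transforms=transforms, degenerate_init=degen)


def _outward_order(k: int, r: int) -> list[tuple[int, int]]:
    """(slide, neighbor-toward-reference) pairs, alternating sides outward."""
    pairs = []
    up = [(i, i - 1) for i in range(r + 1, k)]
    down = [(i, i + 1) for i in range(r - 1, -1, -1)]
    for j in range(max(len(up), len(down))):
        if j < len(up):
            pairs.append(up[j])
        if j < len(down):
            pairs.append(down[j])
    return pairs


def _warped_view(pstack: ProcessedStack, i: int, t: RigidTransform2D) -> SlideView:
    img = warp_image(pstack.images[i], t, background=pstack.background)
    msk = warp_image(pstack.masks[i].mask, t, interpolation="nearest", background=0)
    return SlideView(image=img, mask=msk, index=i, pose=t)


def resolve_flips(
    pstack: ProcessedStack,
    align: StackAlignment,
    backend: FeatureBackend,
    side: int = 252,
    patch: int = 7,
    tie_tol: float = 1e-6,
) -> StackAlignment:
    """Resolve the 180° ambiguity left by ellipse initialization.

    Iterates over adjacent pairs outward from the reference; a slide is
    rotated by 180° about the reference center exactly when that improves
    the cosine similarity of global features with its (already resolved)
    neighbor. The reference slide is never flipped, and a tie keeps the
    unflipped pose. The optimized similarity never decreases.
    """
    r = align.reference_index
    transforms = list(align.transforms)
    flips = list(align.flips_applied)
    feats: dict[int, object] = {}

    def features_of(i: int, t: RigidTransform2D):
        view = _warped_view(pstack, i, t)
        return extract_global_features(view.image, backend, side=side, patch=patch,
                                       background=pstack.background)

    ref_center = fit_enclosing_ellipse(pstack.masks[r]).center
    feats[r] = features_of(r, transforms[r])
    for i, j in _outward_order(pstack.k, r):
        flipped_t = RigidTransform2D(theta=180.0, center=ref_center).compose(transforms[i])
        try:
            f_plain = features_of(i, transforms[i])
            f_flip = features_of(i, flipped_t)
            sim_plain = cosine_similarity(f_plain, feats[j])
            sim_flip = cosine_similarity(f_flip, feats[j])
        except Exception as exc:  # noqa: BLE001 - backend failure leaves pose unchanged
            warnings.warn(f"flip resolution failed for slide {i}: {exc}")
            feats[i] = feats[j]
            align.pair_diagnostics[(i, j)] = {"flip_check": "failed"}
            continue
        if sim_flip > sim_plain + tie_tol:
            transforms[i] = flipped_t
            flips[i] = True
            feats[i] = f_flip
        else:
            feats[i] = f_plain
        align.pair_diagnostics[(i, j)] = {
            "sim_unflipped": sim_plain,
            "sim_flipped": sim_flip,
            "flip": flips[i],
        }
    return StackAlignment(
        reference_index=r,
        transforms=transforms,
        flips_applied=flips,
        deformable=list(align.deformable),
        degenerate_init=list(align.degenerate_init),
        pair_diagnostics=align.pair_diagnostics,
    )


# ---------------------------------------------------------------------------
# RANSAC rigid estimation
# ---------------------------------------------------------------------------


def _procrustes_rigid(pa: np.ndarray, pb: np.ndarray) -> RigidTransform2D:
    """Closed-form least-squares rigid map (pa -> pb), reflection excluded.

    Rotation from the SVD of the cross-covariance with the reflection
    branch rejected (det forced to +1); translation from the centroids.
    """
    ca, cb = pa.mean(axis=0), pb.mean(axis=0)
    h = (pa - ca).T @ (pb - cb)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, d]) @ u.T
    theta = np.rad2deg(np.arctan2(rot[1, 0], rot[0, 0]))
    t = cb - rot @ ca
    return RigidTransform2D(theta=float(theta), tx=float(t[0]), ty=float(t[1]), center=(0.0, 0.0))


def estimate_rigid(
    matches: MatchSet,
    seed: int = 0,
    threshold: float = 3.0,
    iterations: int = 1000,
    min_consensus_fraction: float = 0.10,
) -> tuple[RigidTransform2D, MatchSet]:
    """RANSAC rigid estimation from candidate correspondences.

    Repeatedly samples 2 matches, builds the closed-form rigid candidate,
    and counts matches with residual below the empirical ``threshold``
    (pixels at processing resolution). The best consensus set is refined by
    closed-form least squares over all its inliers, inliers are recomputed
    under the refined model, and the refinement repeated once. Inlier flags
    are set on the returned match set. Deterministic given the seed.

    A consensus must contain at least 3 matches *and* at least
    ``min_consensus_fraction`` of all candidates: a "best" model explaining
    only a sliver of the matches is noise (typical when adjacent sections
    genuinely differ, e.g. near a specimen's ends where the cross-section
    shrinks radially — motion no rigid model fits), and the caller's
    fallback pose is then more trustworthy than the spurious fit.
    """
    if matches.m < 3:
        raise InsufficientMatchesError(f"need >= 3 matches, got {matches.m}")
    pa, pb = matches.points_a, matches.points_b
    m = matches.m
    rng = np.random.default_rng(seed)
    idx = np.array([rng.choice(m, size=2, replace=False) for _ in range(iterations)])
    va = pa[idx[:, 1]] - pa[idx[:, 0]]
    vb = pb[idx[:, 1]] - pb[idx[:, 0]]
    ok = (np.linalg.norm(va, axis=1) > 1e-9) & (np.linalg.norm(vb, axis=1) > 1e-9)
    thetas = np.arctan2(vb[:, 1], vb[:, 0]) - np.arctan2(va[:, 1], va[:, 0])
    cos, sin = np.cos(thetas), np.sin(thetas)
    # candidate translation from the first sampled point of each pair
    a0, b0 = pa[idx[:, 0]], pb[idx[:, 0]]
    tx = b0[:, 0] - (cos * a0[:, 0] - sin * a0[:, 1])
    ty = b0[:, 1] - (sin * a0[:, 0] + cos * a0[:, 1])
    # residuals for all candidates x all matches
    rx = cos[:, None] * pa[None, :, 0] - sin[:, None] * pa[None, :, 1] + tx[:, None] - pb[None, :, 0]
    ry = sin[:, None] * pa[None, :, 0] + cos[:, None] * pa[None, :, 1] + ty[:, None] - pb[None, :, 1]
    res2 = rx * rx + ry * ry
    inl = res2 < threshold**2
    counts = np.where(ok, inl.sum(axis=1), -1)
    best = int(np.argmax(counts))
    # a 2-point sample plus a handful of coincidences can "explain" 3-5
    # matches in any noise; demand 6 when that many candidates exist at all
    needed = max(3, min(6, m), int(np.ceil(min_consensus_fraction * m)))
    if counts[best] < needed:
        raise NoConsensusError(
            f"best consensus has {max(counts[best], 0)}/{m} inliers (need >= {needed})"
        )
    inliers = inl[best]
    for _ in range(2):
        t = _procrustes_rigid(pa[inliers], pb[inliers])
        res = np.linalg.norm(t.apply(pa) - pb, axis=1)
        new_inliers = res < threshold
        if new_inliers.sum() < 3:
            break
        if np.array_equal(new_inliers, inliers):
            inliers = new_inliers
            break
        inliers = new_inliers
    t = _procrustes_rigid(pa[inliers], pb[inliers])
    updated = MatchSet(pa, pb, matches.confidence, inlier=inliers)
    return t, updated


# ---------------------------------------------------------------------------
# Iterative outward stack alignment
# ---------------------------------------------------------------------------


def align_stack(
    pstack: ProcessedStack,
    align: StackAlignment,
    backend: FeatureBackend,
    seed: int = 0,
    threshold: float = 3.0,
    iterations: int = 1000,
) -> StackAlignment:
    """Finetune all slides by outward iterative pairwise registration.

    With ``r`` the reference index, slide ``r+1`` is aligned to ``r``, then
    ``r+2`` to the already-aligned ``r+1``, and symmetrically down the other
    side, until all slides are registered. Each pairwise step matches the
    slide as currently posed against its aligned neighbor, estimates the
    residual rigid transform by RANSAC in the shared frame, and composes
    that refinement onto the slide's current (initialization + flip) pose.
    A pair with too few matches or no consensus keeps the initialization
    pose and is recorded in the diagnostics.
    """
    r = align.reference_index
    transforms = list(align.transforms)
    diags = dict(align.pair_diagnostics)
    rng = np.random.default_rng(seed)
    for i, j in _outward_order(pstack.k, r):
        pair_seed = int(rng.integers(0, 2**31 - 1))
        view_i = _warped_view(pstack, i, transforms[i])
        view_j = _warped_view(pstack, j, transforms[j])
        try:
            matches = dense_match(view_i, view_j, backend, seed=pair_seed)
            residual, matches = estimate_rigid(matches, seed=pair_seed, threshold=threshold,
                                               iterations=iterations)
            transforms[i] = residual.compose(transforms[i])
            diags[(i, j)] = {
                **diags.get((i, j), {}),
                "n_matches": matches.m,
                "n_inliers": int(matches.inlier.sum()),
                "mean_residual": float(
                    np.linalg.norm(
                        residual.apply(matches.points_a[matches.inlier]) - matches.points_b[matches.inlier],
                        axis=1,
                    ).mean()
                ),
                "residual_theta": residual.theta,
            }
        except (InsufficientMatchesError, NoConsensusError) as exc:
            warnings.warn(f"pairwise registration {i}->{j} failed ({exc}); keeping initialization pose")
            diags[(i, j)] = {**diags.get((i, j), {}), "failed": str(exc)}
    return StackAlignment(
        reference_index=r,
        transforms=transforms,
        flips_applied=list(align.flips_applied),
        deformable=list(align.deformable),
        degenerate_init=list(align.degenerate_init),
        pair_diagnostics=diags,
    )


# ---------------------------------------------------------------------------
# Optional TPS refinement
# ---------------------------------------------------------------------------


def refine_deformable(
    shape: tuple[int, int],
    matches: MatchSet,
    grid_spacing: float = 32.0,
    regularization: float = 1e-3,
) -> DeformationField:
    """Fit a backward TPS field from inlier correspondences.

    ``matches`` relate the moving slide (a, already rigidly aligned) to the
    fixed neighbor (b) in the shared frame; the backward field stored on a
    Cartesian grid maps output (fixed-frame) coordinates to the moving
    slide's pre-deformation coordinates. Fewer than 4 non-collinear inliers
    refuse refinement and return the identity field.
    """
    w, h = shape
    sel = matches.inlier if matches.inlier.any() else np.ones(matches.m, dtype=bool)
    fixed, moving = matches.points_b[sel], matches.points_a[sel]
    identity = DeformationField.identity_on_grid(shape, grid_spacing)
    if sel.sum() < 4:
        return identity
    span = fixed - fixed.mean(axis=0)
    if np.linalg.matrix_rank(span, tol=1e-6) < 2:
        return identity
    weights, affine = tps_fit(fixed, moving, regularization=regularization)
    from .transform import tps_evaluate

    nodes = identity.control_sources
    targets = tps_evaluate(nodes, fixed, weights, affine)
    return DeformationField(nodes, targets, grid_spacing, regularization)
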