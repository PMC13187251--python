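"""Feature backends: global patch-grid descriptors and dense matching.

Alignment is driven by *global* features — coarse descriptors of tissue
architecture on a token grid — rather than local keypoints, because
sparsely sampled adjacent sections do not share fine landmarks while their
coarse anatomy persists. This module defines the backend contract and ships
three implementations:

``oracle``
    Emits planted ground-truth correspondences (plus a configurable outlier
    fraction) from a known per-slide geometry; used to validate the
    registration machinery independently of descriptor quality.
``classical``
    Deterministic, weight-free per-cell descriptors (mean RGB, luminance
    spread, gradient-orientation histogram) with mutual-nearest-neighbor
    dense matching and optional phase-correlation subpixel refinement.
``pretrained``
    Optional plug-in contract for a ViT-style token-grid extractor with a
    fine-feature pyramid and a learned dense matcher. Requires a deep
    learning runtime and downloaded weights; everything else in the package
    runs without it.

Coordinates produced by dense matching are in processed-frame pixel units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _scipy_stats
from skimage.registration import phase_cross_correlation
from sklearn.decomposition import PCA

from .transform import RigidTransform2D


class CapabilityError(RuntimeError):
    """Backend asked for an operation it does not support."""


class BackendUnavailableError(RuntimeError):
    """Backend exists as a contract but its runtime is not installed."""


class InsufficientMatchesError(RuntimeError):
    """Fewer than 3 candidate correspondences; caller decides the fallback."""


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


@dataclass
class FeatureMap:
    """g x g grid of d-dimensional patch embeddings."""

    grid: np.ndarray  # (g, g, d)
    patch_size: int
    source_resolution: int
    backend_id: str

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        g = self.source_resolution // self.patch_size
        if self.grid.shape[:2] != (g, g):
            raise ValueError(
                f"grid shape {self.grid.shape[:2]} != floor(side/patch) = {g}"
            )
        if self.grid.shape[2] < 3:
            raise ValueError("embeddings must have d >= 3")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("non-finite feature values")

    @property
    def g(self) -> int:
        return self.grid.shape[0]

    @property
    def d(self) -> int:
        return self.grid.shape[2]


@dataclass
class MatchSet:
    """Paired 2-D correspondences between two slides with confidences."""

    points_a: np.ndarray  # (m, 2)
    points_b: np.ndarray  # (m, 2)
    confidence: np.ndarray  # (m,) in [0, 1]
    inlier: np.ndarray = None  # (m,) bool, set by RANSAC

    def __post_init__(self) -> None:
        self.points_a = np.atleast_2d(np.asarray(self.points_a, dtype=float))
        self.points_b = np.atleast_2d(np.asarray(self.points_b, dtype=float))
        self.confidence = np.asarray(self.confidence, dtype=float)
        if not (len(self.points_a) == len(self.points_b) == len(self.confidence)):
            raise ValueError("points_a, points_b, confidence must have equal length")
        if self.inlier is None:
            self.inlier = np.zeros(len(self.points_a), dtype=bool)
        self.inlier = np.asarray(self.inlier, dtype=bool)

    @property
    def m(self) -> int:
        return len(self.points_a)


@dataclass
class SlideView:
    """A slide raster as currently posed, plus its identity in the stack.

    ``pose`` maps the slide's processed frame to the frame in which
    ``image`` is rendered (identity when the image is unwarped); the oracle
    backend uses it to express planted correspondences in view coordinates.
    """

    image: np.ndarray
    mask: np.ndarray | None = None
    index: int = 0
    pose: RigidTransform2D = field(default_factory=RigidTransform2D)


# ---------------------------------------------------------------------------
# Backend contract
# ---------------------------------------------------------------------------


class FeatureBackend:
    """Contract all backends implement; see module docstring."""

    backend_id: str = "base"
    capabilities: frozenset = frozenset()
    deterministic: bool = True

    def global_features(self, image: np.ndarray, patch: int) -> FeatureMap:
        raise CapabilityError(f"backend {self.backend_id!r} has no global_descriptor capability")

    def dense_match(self, a: SlideView, b: SlideView, seed: int) -> MatchSet:
        raise CapabilityError(f"backend {self.backend_id!r} has no dense_match capability")


def resize_to_square(
    image: np.ndarray, side: int, background: Sequence[int] = (255, 255, 255)
) -> tuple[np.ndarray, float, tuple[float, float]]:
    """Aspect-preserving resize onto a side x side canvas.

    Returns ``(canvas, scale, (dx, dy))`` where input point p maps to
    ``p * scale + (dx, dy)`` on the canvas.
    """
    from skimage.transform import resize as _resize

    h, w = image.shape[:2]
    scale = side / max(h, w)
    nh, nw = max(1, round(h * scale)), max(1, round(w * scale))
    res = _resize(image.astype(float), (nh, nw) + image.shape[2:], order=1,
                  anti_aliasing=scale < 1, preserve_range=True)
    canvas = np.empty((side, side) + image.shape[2:], dtype=np.uint8)
    canvas[:] = np.asarray(background, dtype=np.uint8)
    dy, dx = (side - nh) // 2, (side - nw) // 2
    canvas[dy : dy + nh, dx : dx + nw] = np.clip(np.rint(res), 0, 255).astype(np.uint8)
    return canvas, scale, (float(dx), float(dy))


def extract_global_features(
    image: np.ndarray,
    backend: FeatureBackend,
    side: int = 1036,
    patch: int = 14,
    background: Sequence[int] = (255, 255, 255),
) -> FeatureMap:
    """Resample an image to ``side`` x ``side`` and extract the token grid.

    The grid is ``g = floor(side / patch)`` tokens per axis (74 for the
    default 1036 / 14 configuration).
    """
    if "global_descriptor" not in backend.capabilities:
        raise CapabilityError(f"backend {backend.backend_id!r} has no global_descriptor capability")
    if image.shape[:2] != (side, side):
        image, _, _ = resize_to_square(image, side, background)
    return backend.global_features(image, patch)


def cosine_similarity(a: FeatureMap, b: FeatureMap, aggregation: str = "flatten") -> float:
    """Cosine similarity of two feature maps.

    ``flatten`` (default) compares the full flattened g*g*d vectors —
    token-order sensitive, hence rotation sensitive, which is what makes a
    180° pose difference discriminable. ``mean`` pools tokens first.
    """
    if a.grid.shape != b.grid.shape:
        raise ValueError(f"shape mismatch: {a.grid.shape} vs {b.grid.shape}")
    if aggregation == "flatten":
        va, vb = a.grid.ravel(), b.grid.ravel()
    elif aggregation == "mean":
        va, vb = a.grid.mean(axis=(0, 1)), b.grid.mean(axis=(0, 1))
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    denom = np.linalg.norm(va) * np.linalg.norm(vb)
    if denom == 0:
        return 0.0
    return float(np.dot(va, vb) / denom)


def dense_match(a: SlideView, b: SlideView, backend: FeatureBackend, seed: int = 0) -> MatchSet:
    """Find candidate correspondences between two posed slide views."""
    if "dense_match" not in backend.capabilities:
        raise CapabilityError(f"backend {backend.backend_id!r} has no dense_match capability")
    matches = backend.dense_match(a, b, seed)
    if matches.m < 3:
        raise InsufficientMatchesError(f"only {matches.m} candidate matches")
    return matches


# ---------------------------------------------------------------------------
# Classical backend
# ---------------------------------------------------------------------------


def _luminance(image: np.ndarray) -> np.ndarray:
    return image.astype(float) @ np.array([0.2125, 0.7154, 0.0721])


def grid_descriptors(image: np.ndarray, patch: int, zero_background: bool = False) -> np.ndarray:
    """Per-cell descriptors on a g x g grid: d = 12 per cell.

    Concatenation of mean RGB (3), luminance standard deviation (1) and an
    8-bin gradient-orientation histogram (8), L2-normalized per cell. Cell
    statistics depend only on pixels inside (or bordering) the cell, so the
    grid is shift-equivariant under whole-cell translations away from the
    image border.

    With ``zero_background`` set, cells of (near-)white featureless glass
    are zeroed so they contribute nothing to whole-map comparisons — a
    large empty background would otherwise dominate the cosine similarity
    and mask the tissue signal the comparison is meant to capture.
    """
    g = min(image.shape[0], image.shape[1]) // patch
    img = image[: g * patch, : g * patch].astype(float)
    cells = img.reshape(g, patch, g, patch, 3)
    mean_rgb = cells.mean(axis=(1, 3)) / 255.0
    lum = _luminance(img)
    lum_cells = lum.reshape(g, patch, g, patch)
    lum_mean = lum_cells.mean(axis=(1, 3))
    lum_std = lum_cells.std(axis=(1, 3))[..., None] / 255.0
    gy, gx = np.gradient(lum)
    mag = np.hypot(gx, gy)
    ang = np.mod(np.arctan2(gy, gx), 2 * np.pi)
    bins = np.minimum((ang / (2 * np.pi) * 8).astype(int), 7)
    cy = np.repeat(np.arange(g), patch)[:, None]
    cx = np.repeat(np.arange(g), patch)[None, :]
    hist = np.zeros((g, g, 8))
    np.add.at(hist, (np.broadcast_to(cy, mag.shape), np.broadcast_to(cx, mag.shape), bins), mag)
    hist = hist / (hist.sum(axis=2, keepdims=True) + 1e-9)
    desc = np.concatenate([mean_rgb, lum_std, hist], axis=2)
    norm = np.linalg.norm(desc, axis=2, keepdims=True)
    desc = desc / np.maximum(norm, 1e-12)
    if zero_background:
        desc[(lum_mean > 245) & (lum_std[..., 0] < 0.02)] = 0.0
    return desc


class ClassicalBackend(FeatureBackend):
    """Weight-free deterministic descriptors; see :func:`grid_descriptors`."""

    backend_id = "classical"
    capabilities = frozenset({"global_descriptor", "dense_match"})
    deterministic = True

    def __init__(
        self,
        match_patch: int = 8,
        min_cell_coverage: float = 0.6,
        min_similarity: float = 0.9,
        refine_subpixel: bool = True,
        search_radius: float = 32.0,
    ):
        self.match_patch = match_patch
        self.min_cell_coverage = min_cell_coverage
        self.min_similarity = min_similarity
        self.refine_subpixel = refine_subpixel
        # dense matching happens on roughly prealigned views, so candidate
        # correspondences are searched within this radius (px); it caps the
        # residual motion the matches can express.
        self.search_radius = search_radius

    def global_features(self, image: np.ndarray, patch: int) -> FeatureMap:
        side = min(image.shape[:2])
        return FeatureMap(grid_descriptors(image, patch, zero_background=True), patch, side, self.backend_id)

    def _cells(self, view: SlideView, patch: int):
        desc = grid_descriptors(view.image, patch)
        g = desc.shape[0]
        if view.mask is not None:
            m = view.mask[: g * patch, : g * patch].astype(float)
            cov = m.reshape(g, patch, g, patch).mean(axis=(1, 3))
            keep = cov >= self.min_cell_coverage
        else:
            keep = np.ones((g, g), dtype=bool)
        iy, ix = np.nonzero(keep)
        centers = np.column_stack([ix * patch + (patch - 1) / 2.0, iy * patch + (patch - 1) / 2.0])
        return desc[iy, ix], centers

    def dense_match(self, a: SlideView, b: SlideView, seed: int = 0) -> MatchSet:
        patch = self.match_patch
        da, ca = self._cells(a, patch)
        db, cb = self._cells(b, patch)
        if len(da) == 0 or len(db) == 0:
            return MatchSet(np.empty((0, 2)), np.empty((0, 2)), np.empty(0))
        sim = da @ db.T
        if self.search_radius is not None and np.isfinite(self.search_radius):
            d2 = ((ca[:, None, :] - cb[None, :, :]) ** 2).sum(-1)
            sim = np.where(d2 <= self.search_radius**2, sim, -np.inf)
        best_b = np.argmax(sim, axis=1)
        best_a = np.argmax(sim, axis=0)
        ia = np.arange(len(da))
        mutual = best_a[best_b[ia]] == ia
        sims = sim[ia, best_b]
        keep = mutual & (sims >= self.min_similarity)
        pa, pb = ca[keep], cb[best_b[keep]]
        conf = np.clip((sims[keep] - self.min_similarity) / (1 - self.min_similarity + 1e-12), 0, 1)
        if self.refine_subpixel and len(pa):
            pb = self._refine(a.image, b.image, pa, pb, patch)
        return MatchSet(pa, pb, conf)

    def _refine(self, img_a, img_b, pa, pb, patch):
        """Phase-correlation subpixel correction of matched cell centers."""
        lum_a, lum_b = _luminance(img_a), _luminance(img_b)
        half = int(1.5 * patch)
        out = pb.copy()
        for i, ((xa, ya), (xb, yb)) in enumerate(zip(pa, pb)):
            ax, ay, bx, by = int(round(xa)), int(round(ya)), int(round(xb)), int(round(yb))
            if min(ax, ay, bx, by) < half or ax + half > lum_a.shape[1] or ay + half > lum_a.shape[0] \
                    or bx + half > lum_b.shape[1] or by + half > lum_b.shape[0]:
                continue
            wa = lum_a[ay - half : ay + half, ax - half : ax + half]
            wb = lum_b[by - half : by + half, bx - half : bx + half]
            shift, _, _ = phase_cross_correlation(wa, wb, upsample_factor=8, normalization=None)
            dy, dx = shift
            if abs(dx) <= patch and abs(dy) <= patch:
                # shift registers wb onto wa; the b-point matching pa sits at pb - shift
                out[i] = (xb - dx, yb - dy)
        return out


# ---------------------------------------------------------------------------
# Oracle backend
# ---------------------------------------------------------------------------


class OracleBackend(FeatureBackend):
    """Ground-truth correspondence generator for validation.

    Holds the true per-slide transform ``G_i`` mapping a common (section)
    frame into slide ``i``'s processed frame. A true correspondence between
    slides is then ``q_b = P_b(G_b(G_a^{-1}(P_a^{-1}(q_a))))`` for view poses
    ``P``. A configured fraction of matches is replaced by uniform outliers,
    and Gaussian noise may be added to the planted inliers. Global
    descriptors delegate to the classical routine so the full pipeline
    (including flip resolution) runs under this backend.
    """

    backend_id = "oracle"
    capabilities = frozenset({"global_descriptor", "dense_match"})
    deterministic = True  # given identical seeds

    def __init__(
        self,
        true_transforms: Sequence[RigidTransform2D],
        n_matches: int = 100,
        outlier_fraction: float = 0.0,
        noise_sigma: float = 0.0,
    ):
        self.true_transforms = list(true_transforms)
        self.n_matches = n_matches
        self.outlier_fraction = outlier_fraction
        self.noise_sigma = noise_sigma
        self._classical = ClassicalBackend()

    def global_features(self, image: np.ndarray, patch: int) -> FeatureMap:
        fm = self._classical.global_features(image, patch)
        return FeatureMap(fm.grid, fm.patch_size, fm.source_resolution, self.backend_id)

    def dense_match(self, a: SlideView, b: SlideView, seed: int = 0) -> MatchSet:
        rng = np.random.default_rng(seed)
        h, w = a.image.shape[:2]
        if a.mask is not None and a.mask.any():
            ys, xs = np.nonzero(a.mask)
            idx = rng.choice(len(xs), size=min(self.n_matches * 2, len(xs)), replace=False)
            qa = np.column_stack([xs[idx], ys[idx]]).astype(float)
        else:
            qa = rng.uniform(0, [w - 1, h - 1], size=(self.n_matches * 2, 2))
        ga, gb = self.true_transforms[a.index], self.true_transforms[b.index]
        pa = a.pose.inverse().apply(qa)
        qb = b.pose.apply(gb.apply(ga.inverse().apply(pa)))
        hb, wb = b.image.shape[:2]
        inside = (qb[:, 0] >= 0) & (qb[:, 0] <= wb - 1) & (qb[:, 1] >= 0) & (qb[:, 1] <= hb - 1)
        qa, qb = qa[inside][: self.n_matches], qb[inside][: self.n_matches]
        m = len(qa)
        conf = np.full(m, 0.9)
        n_out = int(round(self.outlier_fraction * m))
        if n_out:
            out_idx = rng.choice(m, size=n_out, replace=False)
            qb[out_idx] = rng.uniform(0, [wb - 1, hb - 1], size=(n_out, 2))
            conf[out_idx] = 0.3
        if self.noise_sigma > 0:
            planted = np.ones(m, dtype=bool)
            if n_out:
                planted[out_idx] = False
            qb[planted] += rng.normal(0, self.noise_sigma, size=(planted.sum(), 2))
        return MatchSet(qa, qb, conf)


class PretrainedBackend(FeatureBackend):
    """Contract for a ViT token-grid extractor + learned dense matcher.

    Needs a deep learning runtime (torch) and downloaded weights; neither is
    bundled. Constructing it without them raises
    :class:`BackendUnavailableError`, and the rest of the package is fully
    functional with the oracle and classical backends.
    """

    backend_id = "pretrained"
    capabilities = frozenset({"global_descriptor", "dense_match"})
    deterministic = False

    def __init__(self, **kwargs):
        try:
            import torch  # noqa: F401
        except ImportError as exc:
            raise BackendUnavailableError(
                "the pretrained backend needs torch and model weights; "
                "use the 'classical' or 'oracle' backend instead"
            ) from exc
        raise BackendUnavailableError("no pretrained weights bundled with this package")


_BACKENDS = {
    "classical": ClassicalBackend,
    "oracle": OracleBackend,
    "pretrained": PretrainedBackend,
}


def get_backend(name: str, **kwargs) -> FeatureBackend:
    """Instantiate a registered feature backend by config key."""
    if name not in _BACKENDS:
        raise ValueError(f"unknown feature backend {name!r}; choose from {sorted(_BACKENDS)}")
    return _BACKENDS[name](**kwargs)


# ---------------------------------------------------------------------------
# PCA visualization
# ---------------------------------------------------------------------------


def pca_rgb(maps: Sequence[FeatureMap]) -> list[np.ndarray]:
    """Project token grids onto their three stack-wide principal components.

    The PCA is fitted on the concatenated tokens of all maps so colors are
    comparable across slides; each component's scores are min-max scaled to
    [0, 1] over the whole stack. Component sign is fixed by forcing positive
    skew of the scores; a component with (numerically) zero variance renders
    as constant 0.5.
    """
    if not maps:
        raise ValueError("need at least one feature map")
    g, d = maps[0].g, maps[0].d
    if d < 3:
        raise ValueError("need d >= 3 for a 3-component projection")
    if any((m.g, m.d) != (g, d) for m in maps):
        raise ValueError("all maps must share g and d")
    tokens = np.concatenate([m.grid.reshape(-1, d) for m in maps], axis=0)
    pca = PCA(n_components=3, svd_solver="full", random_state=0)
    scores = pca.fit_transform(tokens)
    for c in range(3):
        if _scipy_stats.skew(scores[:, c]) < 0:
            scores[:, c] = -scores[:, c]
    lo, hi = scores.min(axis=0), scores.max(axis=0)
    span = hi - lo
    scaled = np.where(span > 1e-9, (scores - lo) / np.maximum(span, 1e-30), 0.5)
    return [chunk.reshape(g, g, 3) for chunk in np.split(scaled, len(maps), axis=0)]
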