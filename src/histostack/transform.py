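"""Resolution-scalable 2-D transforms and tile-streamed warping.

Geometry core of the reconstruction pipeline: rigid (rotation + translation)
transforms about an explicit center, thin-plate-spline (TPS) deformation
fields with backward-map semantics, linear rescaling of both across pyramid
resolution levels, dense backward coordinate maps decomposable into
independent tiles, and through-plane interpolation of registered binary
masks into a contiguous 3-D volume.

Conventions
-----------
* Coordinates are ``(x, y)`` = ``(column, row)``, 0-based, pixel-center.
* All transforms use forward semantics (``apply`` maps moving-frame points
  into the fixed frame); warping uses the inverse as a backward (pull) map,
  so every output pixel independently stores the source coordinate to
  sample from and the mapping decomposes into tiles with no boundary
  dependence.
* Angles are degrees, normalized to ``(-180, 180]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Literal, Sequence

import numpy as np
from scipy import ndimage


def wrap_angle(theta: float | np.ndarray, period: float = 360.0):
    """Normalize an angle (degrees) to the half-open interval (-period/2, period/2]."""
    wrapped = np.mod(np.asarray(theta, dtype=float), period)
    wrapped = np.where(wrapped > period / 2.0, wrapped - period, wrapped)
    if np.ndim(theta) == 0:
        return float(wrapped)
    return wrapped


# ---------------------------------------------------------------------------
# Rigid transforms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RigidTransform2D:
    """Rotation by ``theta`` degrees about ``center`` followed by translation.

    ``p' = R(theta) @ (p - center) + center + (tx, ty)``

    The linear part is a pure rotation: determinant 1, both singular values 1.
    Scale and shear are not representable, by construction.
    """

    theta: float = 0.0
    tx: float = 0.0
    ty: float = 0.0
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "theta", wrap_angle(self.theta))

    @property
    def rotation_matrix(self) -> np.ndarray:
        rad = np.deg2rad(self.theta)
        c, s = np.cos(rad), np.sin(rad)
        return np.array([[c, -s], [s, c]])

    def as_matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix acting on column vectors ``(x, y, 1)``."""
        rot = self.rotation_matrix
        cen = np.asarray(self.center, dtype=float)
        shift = cen + np.array([self.tx, self.ty]) - rot @ cen
        mat = np.eye(3)
        mat[:2, :2] = rot
        mat[:2, 2] = shift
        return mat

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map ``(n, 2)`` points (or a single point) through the transform."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        cen = np.asarray(self.center, dtype=float)
        out = (pts - cen) @ self.rotation_matrix.T + cen + np.array([self.tx, self.ty])
        return out[0] if np.ndim(points) == 1 else out

    def inverse(self) -> "RigidTransform2D":
        inv_theta = -self.theta
        rad = np.deg2rad(inv_theta)
        c, s = np.cos(rad), np.sin(rad)
        rot = np.array([[c, -s], [s, c]])
        new_t = -rot @ np.array([self.tx, self.ty])
        return RigidTransform2D(inv_theta, float(new_t[0]), float(new_t[1]), tuple(self.center))

    def compose(self, first: "RigidTransform2D") -> "RigidTransform2D":
        """Return the transform equivalent to applying ``first`` then ``self``."""
        theta = wrap_angle(self.theta + first.theta)
        cen = np.asarray(first.center, dtype=float)
        mapped = self.apply(first.apply(cen))
        return RigidTransform2D(theta, float(mapped[0] - cen[0]), float(mapped[1] - cen[1]), tuple(cen))

    def is_identity(self, tol: float = 1e-9) -> bool:
        return abs(wrap_angle(self.theta)) < tol and abs(self.tx) < tol and abs(self.ty) < tol

    def to_dict(self) -> dict:
        return {
            "theta": float(self.theta),
            "tx": float(self.tx),
            "ty": float(self.ty),
            "center": [float(self.center[0]), float(self.center[1])],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform2D":
        return cls(d["theta"], d["tx"], d["ty"], tuple(d["center"]))

    @classmethod
    def identity(cls) -> "RigidTransform2D":
        return cls()


def scale_rigid(t: RigidTransform2D, factor: float) -> RigidTransform2D:
    """Rescale a rigid transform to another resolution level.

    The rotation angle is scale-invariant; translations and the rotation
    center are lengths, so they scale linearly with resolution.
    """
    if factor <= 0:
        raise ValueError(f"scale factor must be positive, got {factor}")
    return RigidTransform2D(
        t.theta,
        t.tx * factor,
        t.ty * factor,
        (t.center[0] * factor, t.center[1] * factor),
    )


# ---------------------------------------------------------------------------
# Thin-plate-spline deformation fields
# ---------------------------------------------------------------------------


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    # U(r) = r^2 log r, written on squared distances; U(0) = 0.
    out = np.zeros_like(r2)
    pos = r2 > 0
    out[pos] = 0.5 * r2[pos] * np.log(r2[pos])
    return out


def tps_fit(sources: np.ndarray, targets: np.ndarray, regularization: float = 0.0):
    """Fit TPS coefficients mapping ``sources`` (n,2) onto ``targets`` (n,2).

    Returns ``(weights, affine)`` where ``weights`` is (n, 2) and ``affine``
    is (3, 2) holding the constant + linear part. With zero regularization
    the fitted map interpolates the data exactly and reproduces any affine
    map without bending.
    """
    src = np.asarray(sources, dtype=float)
    tgt = np.asarray(targets, dtype=float)
    n = len(src)
    if n < 3:
        raise ValueError("TPS needs at least 3 control points")
    d2 = ((src[:, None, :] - src[None, :, :]) ** 2).sum(-1)
    k = _tps_kernel(d2)
    if regularization > 0:
        k = k + regularization * np.eye(n)
    p = np.hstack([np.ones((n, 1)), src])
    sys = np.zeros((n + 3, n + 3))
    sys[:n, :n] = k
    sys[:n, n:] = p
    sys[n:, :n] = p.T
    rhs = np.zeros((n + 3, 2))
    rhs[:n] = tgt
    sol = np.linalg.solve(sys, rhs)
    return sol[:n], sol[n:]


def tps_evaluate(points: np.ndarray, sources: np.ndarray, weights: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Evaluate a fitted TPS at ``(m, 2)`` query points, row-major order."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    src = np.asarray(sources, dtype=float)
    d2 = ((pts[:, None, :] - src[None, :, :]) ** 2).sum(-1)
    out = _tps_kernel(d2) @ weights
    out += affine[0] + pts @ affine[1:]
    return out


@dataclass
class DeformationField:
    """Backward-map TPS deformation on a Cartesian control grid.

    ``control_sources`` are output-frame grid nodes; ``control_targets`` are
    the source-frame coordinates to sample at each node. The field between
    nodes is the exact TPS interpolant through the nodes, which makes the
    representation linearly rescalable: scaling node coordinates and
    refitting the interpolant is equivalent to scaling the warp itself.
    Invertibility is not guaranteed; only backward sampling is supported.
    """

    control_sources: np.ndarray  # (n, 2) output-frame grid nodes
    control_targets: np.ndarray  # (n, 2) source-frame coordinates
    grid_spacing: float
    regularization: float = 0.0
    _weights: np.ndarray = field(default=None, repr=False)
    _affine: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.control_sources = np.asarray(self.control_sources, dtype=float)
        self.control_targets = np.asarray(self.control_targets, dtype=float)
        if self._weights is None:
            # Exact interpolation through the stored nodes; `regularization`
            # is metadata about how the node values were obtained.
            self._weights, self._affine = tps_fit(self.control_sources, self.control_targets)

    def map_points(self, points: np.ndarray) -> np.ndarray:
        """Backward-map output-frame points to source-frame coordinates."""
        out = tps_evaluate(points, self.control_sources, self._weights, self._affine)
        return out[0] if np.ndim(points) == 1 else out

    def is_identity(self, tol: float = 1e-9) -> bool:
        return bool(np.allclose(self.control_sources, self.control_targets, atol=tol))

    def to_dict(self) -> dict:
        return {
            "control_sources": self.control_sources.tolist(),
            "control_targets": self.control_targets.tolist(),
            "grid_spacing": float(self.grid_spacing),
            "regularization": float(self.regularization),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DeformationField":
        return cls(
            np.asarray(d["control_sources"]),
            np.asarray(d["control_targets"]),
            d["grid_spacing"],
            d.get("regularization", 0.0),
        )

    @classmethod
    def identity_on_grid(cls, shape: tuple[int, int], grid_spacing: float) -> "DeformationField":
        w, h = shape
        xs = np.arange(0.0, w + grid_spacing, grid_spacing)
        ys = np.arange(0.0, h + grid_spacing, grid_spacing)
        gx, gy = np.meshgrid(xs, ys)
        nodes = np.column_stack([gx.ravel(), gy.ravel()])
        return cls(nodes, nodes.copy(), grid_spacing)


def scale_deformable(f: DeformationField, factor: float) -> DeformationField:
    """Rescale a TPS field to another resolution level.

    Node and target coordinates (and the grid spacing) are lengths, so they
    scale linearly; the TPS weights are recomputed from the scaled control
    points alone — no refit against the original matches is needed, because
    the TPS interpolant is equivariant under similarity transforms applied
    to both domain and range.
    """
    if factor <= 0:
        raise ValueError(f"scale factor must be positive, got {factor}")
    return DeformationField(
        f.control_sources * factor,
        f.control_targets * factor,
        f.grid_spacing * factor,
        f.regularization,
    )


# ---------------------------------------------------------------------------
# Backward coordinate maps and tiled warping
# ---------------------------------------------------------------------------


def build_backward_map(
    t: RigidTransform2D | None,
    out_shape: tuple[int, int],
    tile: tuple[int, int, int, int] | None = None,
    deformable: DeformationField | None = None,
) -> np.ndarray:
    """Dense backward coordinate map for a tile of the output image.

    Parameters
    ----------
    t : rigid transform mapping source frame -> output frame (or None for
        identity); the map stores, for each output pixel, the source
        coordinate ``t^{-1}(o)``.
    out_shape : (width, height) of the full output image.
    tile : (x0, y0, w, h) region of the output to compute; defaults to the
        full image. The map restricted to a tile equals the global map on
        that tile — coordinates are computed from absolute output indices,
        so tiling introduces no boundary dependence.
    deformable : optional backward TPS field applied in the output frame
        before the inverse rigid map.

    Returns
    -------
    (h, w, 2) array of source ``(x, y)`` coordinates.
    """
    ow, oh = out_shape
    if tile is None:
        tile = (0, 0, ow, oh)
    x0, y0, tw, th = tile
    if x0 < 0 or y0 < 0 or x0 + tw > ow or y0 + th > oh:
        raise ValueError(f"tile {tile} outside output shape {out_shape}")
    xs = np.arange(x0, x0 + tw, dtype=float)
    ys = np.arange(y0, y0 + th, dtype=float)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    if deformable is not None:
        pts = deformable.map_points(pts)
    if t is not None:
        pts = t.inverse().apply(pts)
    return pts.reshape(th, tw, 2)


def _sample(image: np.ndarray, coords: np.ndarray, order: int, cval) -> np.ndarray:
    """Sample an image (H, W[, C]) at backward-map coords (h, w, 2)."""
    yx = [coords[..., 1], coords[..., 0]]
    if image.ndim == 2:
        out = ndimage.map_coordinates(image.astype(float), yx, order=order, mode="constant", cval=float(cval))
        return out
    channels = []
    cvals = np.broadcast_to(np.asarray(cval, dtype=float).ravel(), (image.shape[2],))
    for c in range(image.shape[2]):
        channels.append(
            ndimage.map_coordinates(
                image[..., c].astype(float), yx, order=order, mode="constant", cval=cvals[c]
            )
        )
    return np.stack(channels, axis=-1)


def warp_image(
    image: np.ndarray,
    t: RigidTransform2D | None,
    out_shape: tuple[int, int] | None = None,
    interpolation: Literal["nearest", "bilinear"] = "bilinear",
    background=255,
    deformable: DeformationField | None = None,
) -> np.ndarray:
    """Monolithic warp: reference against which tiled warping is checked."""
    if out_shape is None:
        out_shape = (image.shape[1], image.shape[0])
    coords = build_backward_map(t, out_shape, deformable=deformable)
    order = 0 if interpolation == "nearest" else 1
    out = _sample(image, coords, order, background)
    if np.issubdtype(image.dtype, np.integer):
        info = np.iinfo(image.dtype)
        out = np.clip(np.rint(out), info.min, info.max).astype(image.dtype)
    elif image.dtype == bool:
        out = out > 0.5
    return out


def iter_tiles(out_shape: tuple[int, int], tile_size: int) -> Iterator[tuple[int, int, int, int]]:
    """Row-major tiling of an output extent into (x0, y0, w, h) tiles."""
    ow, oh = out_shape
    for y0 in range(0, oh, tile_size):
        for x0 in range(0, ow, tile_size):
            yield (x0, y0, min(tile_size, ow - x0), min(tile_size, oh - y0))


def warp_tiled(
    image: np.ndarray,
    t: RigidTransform2D | None,
    tile_size: int = 512,
    out_shape: tuple[int, int] | None = None,
    interpolation: Literal["nearest", "bilinear"] = "bilinear",
    background=255,
    deformable: DeformationField | None = None,
) -> Iterator[tuple[tuple[int, int], np.ndarray]]:
    """Stream a warped image tile by tile.

    Yields ``((x0, y0), tile_pixels)`` in row-major order. Each tile is
    computed from absolute output coordinates with per-pixel backward
    sampling, so the concatenation of tiles is pixel-identical to
    :func:`warp_image` with the same interpolation regardless of tile size.
    Peak live pixels are one tile plus the source region it samples.
    """
    if tile_size < 16:
        raise ValueError("tile_size must be >= 16")
    if out_shape is None:
        out_shape = (image.shape[1], image.shape[0])
    order = 0 if interpolation == "nearest" else 1
    is_int = np.issubdtype(image.dtype, np.integer)
    for x0, y0, tw, th in iter_tiles(out_shape, tile_size):
        coords = build_backward_map(t, out_shape, (x0, y0, tw, th), deformable=deformable)
        out = _sample(image, coords, order, background)
        if is_int:
            info = np.iinfo(image.dtype)
            out = np.clip(np.rint(out), info.min, info.max).astype(image.dtype)
        elif image.dtype == bool:
            out = out > 0.5
        yield (x0, y0), out


def assemble_tiles(tiles, out_shape: tuple[int, int], channels: int | None = None, dtype=None) -> np.ndarray:
    """Collect a tile stream into a single array (test/debug helper)."""
    ow, oh = out_shape
    out = None
    for (x0, y0), block in tiles:
        if out is None:
            shape = (oh, ow) if block.ndim == 2 else (oh, ow, block.shape[2])
            out = np.zeros(shape, dtype=block.dtype if dtype is None else dtype)
        out[y0 : y0 + block.shape[0], x0 : x0 + block.shape[1]] = block
    if out is None:
        raise ValueError("empty tile stream")
    return out


# ---------------------------------------------------------------------------
# Through-plane interpolation for 3-D rendering
# ---------------------------------------------------------------------------


def interpolate_volume(masks: Sequence[np.ndarray], steps_between: int = 0) -> np.ndarray:
    """Build a contiguous binary volume from registered section masks.

    Between each adjacent pair of sections, ``steps_between`` intermediate
    frames are inserted by linear through-plane cross-fading of the two
    binary masks followed by thresholding at 0.5 (tissue vs background).
    ``steps_between=0`` returns the input stack unchanged.
    """
    if steps_between < 0:
        raise ValueError("steps_between must be >= 0")
    stack = [np.asarray(m) > 0 for m in masks]
    if len({m.shape for m in stack}) != 1:
        raise ValueError("all masks must share a shape")
    frames = []
    for a, b in zip(stack[:-1], stack[1:]):
        frames.append(a)
        af, bf = a.astype(float), b.astype(float)
        for j in range(1, steps_between + 1):
            f = j / (steps_between + 1)
            frames.append((1.0 - f) * af + f * bf >= 0.5)
    frames.append(stack[-1])
    return np.stack(frames)
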