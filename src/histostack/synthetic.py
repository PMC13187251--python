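"""Synthetic phantoms with exact ground truth.

Emulates the imaging situation the reconstruction pipeline is built for: a
contiguous organ-like 3-D specimen sectioned at a sparse interval, where
*coarse* anatomy (large smooth structures, thicker than the slice interval)
persists between adjacent sections while *fine* structures (smaller than
the interval) appear and disappear — so adjacent slides share global tissue
architecture but not fine landmarks. Each section is then given an
independent random rigid perturbation (rotation anywhere in 0–360°,
translation), optionally a planted 180° flip, and per-slide stain jitter.
Fiducial rods traverse the full volume and provide exact landmark
coordinates in every section, analogous to laser-induced holes in serially
sectioned calibration datasets.

Everything is deterministic given the seed, and the ground-truth record
stores the exact planted transforms, so every pipeline stage can be scored
without external data. Horizontal mirror flips are never generated: input
slides are assumed mirror-corrected upstream.

The default phantom is 256 x 256 x 96 voxels at 40 µm in-plane and 400 µm
through-plane, sectioned every 4000 µm into 10 slides — small enough to
reconstruct in seconds while preserving the coarse/fine diameter contrast
around the slice interval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .stack_io import SlideStack
from .transform import RigidTransform2D, warp_image

BACKGROUND = np.array([255, 255, 255], dtype=np.uint8)
ORGAN_COLOR = np.array([235, 175, 205], dtype=float)  # eosin-like pink
COARSE_COLOR = np.array([150, 95, 165], dtype=float)  # hematoxylin-like purple
FINE_COLOR = np.array([95, 55, 120], dtype=float)
ROD_COLOR = np.array([40, 30, 50], dtype=float)


@dataclass
class PhantomSpec:
    """Parameters of the synthetic specimen.

    ``volume_shape`` is (Z, Y, X) voxels; ``voxel_um`` the (z, y, x) voxel
    size in µm (anisotropic: through-plane voxels are coarser, matching the
    disparity between section thickness and pixel spacing). Structure size
    invariants are enforced against ``slice_interval_um``: coarse structures
    must span more than one interval in z, fine structures less.
    """

    volume_shape: tuple[int, int, int] = (96, 256, 256)
    voxel_um: tuple[float, float, float] = (400.0, 40.0, 40.0)
    slice_interval_um: float = 4000.0
    organ_semiaxes: tuple[float, float, float] = (0.53, 0.27, 0.40)  # z,y,x fractions
    organ_exponent: float = 2.5
    n_coarse_structures: int = 6
    coarse_z_radius_vox: tuple[int, int] = (8, 16)
    coarse_xy_radius_px: tuple[int, int] = (16, 30)
    n_fine_structures: int = 40
    fine_z_radius_vox: tuple[int, int] = (1, 4)
    fine_xy_radius_px: tuple[int, int] = (3, 6)
    n_fiducials: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        vz = self.voxel_um[0]
        coarse_min_diam = 2 * self.coarse_z_radius_vox[0] * vz
        fine_max_diam = 2 * self.fine_z_radius_vox[1] * vz
        if coarse_min_diam <= self.slice_interval_um:
            raise ValueError(
                f"coarse structure diameter ({coarse_min_diam} µm) must exceed "
                f"the slice interval ({self.slice_interval_um} µm)"
            )
        if fine_max_diam >= self.slice_interval_um:
            raise ValueError(
                f"fine structure diameter ({fine_max_diam} µm) must be below "
                f"the slice interval ({self.slice_interval_um} µm)"
            )

    @property
    def spacing(self) -> float:
        """In-plane pixel spacing, µm/pixel."""
        return self.voxel_um[2]


@dataclass
class GroundTruthRecord:
    """Exact planted geometry of a (possibly perturbed) phantom stack.

    ``transforms[i]`` maps the common section frame into slide ``i``'s
    frame (the perturbation actually applied); applying its inverse restores
    the unperturbed section. ``rotations`` exclude the planted 180° flips,
    which are recorded separately in ``flips``.
    """

    rotations: np.ndarray  # (k,) degrees, flip excluded
    translations: np.ndarray  # (k, 2) px
    flips: np.ndarray  # (k,) bool
    transforms: list[RigidTransform2D]
    landmarks: list[np.ndarray]  # per-slide (m, 2) in slide-frame px

    @property
    def k(self) -> int:
        return len(self.transforms)

    @property
    def total_rotations(self) -> np.ndarray:
        """Planted rotation including the 180° flip component."""
        return self.rotations + 180.0 * self.flips.astype(float)

    def to_dict(self) -> dict:
        return {
            "rotations": self.rotations.tolist(),
            "translations": self.translations.tolist(),
            "flips": self.flips.astype(bool).tolist(),
            "transforms": [t.to_dict() for t in self.transforms],
            "landmarks": [lm.tolist() for lm in self.landmarks],
        }

    def save(self, path: str) -> str:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthRecord":
        return cls(
            rotations=np.asarray(d["rotations"], dtype=float),
            translations=np.asarray(d["translations"], dtype=float),
            flips=np.asarray(d["flips"], dtype=bool),
            transforms=[RigidTransform2D.from_dict(t) for t in d["transforms"]],
            landmarks=[np.asarray(lm, dtype=float) for lm in d["landmarks"]],
        )

    @classmethod
    def load(cls, path: str) -> "GroundTruthRecord":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def identity(cls, k: int, landmarks: list[np.ndarray]) -> "GroundTruthRecord":
        return cls(
            rotations=np.zeros(k),
            translations=np.zeros((k, 2)),
            flips=np.zeros(k, dtype=bool),
            transforms=[RigidTransform2D() for _ in range(k)],
            landmarks=[lm.copy() for lm in landmarks],
        )


# ---------------------------------------------------------------------------
# Volume generation
# ---------------------------------------------------------------------------


def _organ_params(spec: PhantomSpec, rng: np.random.Generator):
    zdim, ydim, xdim = spec.volume_shape
    az = spec.organ_semiaxes[0] * zdim
    ay = spec.organ_semiaxes[1] * ydim
    ax = spec.organ_semiaxes[2] * xdim
    # smooth in-plane drift of the organ center with z: organ-like bending
    phase = rng.uniform(0, 2 * np.pi)
    amp_x, amp_y = rng.uniform(4, 9), rng.uniform(3, 7)
    return az, ay, ax, phase, amp_x, amp_y


def _organ_section(spec: PhantomSpec, z: int, params) -> np.ndarray:
    zdim, ydim, xdim = spec.volume_shape
    az, ay, ax, phase, amp_x, amp_y = params
    cz, cy0, cx0 = (zdim - 1) / 2.0, (ydim - 1) / 2.0, (xdim - 1) / 2.0
    cx = cx0 + amp_x * np.sin(2 * np.pi * z / zdim + phase)
    cy = cy0 + amp_y * np.cos(2 * np.pi * z / zdim + phase)
    n = spec.organ_exponent
    zt = abs(z - cz) / az
    if zt >= 1.0:
        return np.zeros((ydim, xdim), dtype=bool), (cx, cy)
    # in-plane cross-section of the superellipsoid at height z
    shrink = (1.0 - zt**n) ** (1.0 / n)
    yy, xx = np.mgrid[0:ydim, 0:xdim]
    val = (np.abs(xx - cx) / (ax * shrink)) ** n + (np.abs(yy - cy) / (ay * shrink)) ** n
    return val <= 1.0, (cx, cy)


def generate_phantom(spec: PhantomSpec, return_labels: bool = False):
    """Render the phantom volume.

    Returns ``(volume, fiducials)`` — an (Z, Y, X, 3) uint8 RGB volume and
    the (n_fiducials, 2) array of rod (x, y) coordinates, constant across
    sections — or ``(volume, fiducials, labels)`` with a per-voxel structure
    label volume (0 background/stroma, 1..n_coarse the coarse structures,
    then the fine ones) when ``return_labels`` is set.

    The organ is a smoothly bending superellipsoid, asymmetric by
    construction: one coarse structure is planted off-center through the
    full depth so no section is 180°-rotation symmetric (flip detection is
    undecidable on symmetric specimens).
    """
    rng = np.random.default_rng(spec.seed)
    zdim, ydim, xdim = spec.volume_shape
    params = _organ_params(spec, rng)
    organ = np.zeros((zdim, ydim, xdim), dtype=bool)
    centers = []
    for z in range(zdim):
        organ[z], c = _organ_section(spec, z, params)
        centers.append(c)
    labels = np.zeros((zdim, ydim, xdim), dtype=np.int16)

    az, ay, ax = params[0], params[1], params[2]
    mid = zdim // 2
    cx_mid, cy_mid = centers[mid]

    def paint_blob(idx, czb, cyb, cxb, rz, ry, rx):
        z0, z1 = max(0, int(czb - rz)), min(zdim, int(czb + rz) + 1)
        y0, y1 = max(0, int(cyb - ry)), min(ydim, int(cyb + ry) + 1)
        x0, x1 = max(0, int(cxb - rx)), min(xdim, int(cxb + rx) + 1)
        zz, yy, xx = np.mgrid[z0:z1, y0:y1, x0:x1]
        e = ((zz - czb) / rz) ** 2 + ((yy - cyb) / ry) ** 2 + ((xx - cxb) / rx) ** 2
        inside = (e <= 1.0) & organ[z0:z1, y0:y1, x0:x1]
        labels[z0:z1, y0:y1, x0:x1][inside] = idx

    # asymmetry anchor: off-center coarse structure spanning the full depth
    paint_blob(1, (zdim - 1) / 2.0, cy_mid + 0.45 * ay, cx_mid + 0.55 * ax,
               rz=0.9 * az, ry=0.35 * ay, rx=0.30 * ax)
    label = 2
    for _ in range(spec.n_coarse_structures - 1):
        rz = rng.integers(*spec.coarse_z_radius_vox, endpoint=True)
        ry = rng.integers(*spec.coarse_xy_radius_px, endpoint=True)
        rx = rng.integers(*spec.coarse_xy_radius_px, endpoint=True)
        czb = rng.uniform(0.2 * zdim, 0.8 * zdim)
        cyb = cy_mid + rng.uniform(-0.6, 0.6) * ay
        cxb = cx_mid + rng.uniform(-0.6, 0.6) * ax
        paint_blob(label, czb, cyb, cxb, rz, ry, rx)
        label += 1
    fine_start = label
    for _ in range(spec.n_fine_structures):
        rz = rng.integers(*spec.fine_z_radius_vox, endpoint=True)
        ry = rng.integers(*spec.fine_xy_radius_px, endpoint=True)
        rx = rng.integers(*spec.fine_xy_radius_px, endpoint=True)
        czb = rng.uniform(0.1 * zdim, 0.9 * zdim)
        cyb = cy_mid + rng.uniform(-0.7, 0.7) * ay
        cxb = cx_mid + rng.uniform(-0.7, 0.7) * ax
        paint_blob(label, czb, cyb, cxb, rz, ry, rx)
        label += 1

    # color rendering: smooth texture noise over the organ base color
    noise = ndimage.gaussian_filter(rng.normal(0, 1, (zdim, ydim, xdim)), sigma=(0, 2, 2))
    noise = 12.0 * noise / max(np.abs(noise).max(), 1e-9)
    volume = np.empty((zdim, ydim, xdim, 3), dtype=np.uint8)
    volume[:] = BACKGROUND
    organ_rgb = np.clip(ORGAN_COLOR[None, :] + noise[organ][:, None], 0, 255)
    volume[organ] = organ_rgb.astype(np.uint8)
    coarse = (labels >= 1) & (labels < fine_start)
    fine = labels >= fine_start
    volume[coarse] = np.clip(COARSE_COLOR + noise[coarse][:, None] * 0.5, 0, 255).astype(np.uint8)
    volume[fine] = np.clip(FINE_COLOR + noise[fine][:, None] * 0.5, 0, 255).astype(np.uint8)

    # angular asymmetry: darken a 70° sector about the organ center at every
    # z, so no cross-section (including the small end sections, which the
    # planted blobs may miss) is 180°-rotation symmetric
    sector_angle = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:ydim, 0:xdim]
    for z in range(zdim):
        cx, cy = centers[z]
        ang = np.arctan2(yy - cy, xx - cx)
        diff = np.mod(ang - sector_angle + np.pi, 2 * np.pi) - np.pi
        wedge = organ[z] & (np.abs(diff) < np.deg2rad(35))
        volume[z][wedge] = (volume[z][wedge].astype(float) * 0.82).astype(np.uint8)

    # fiducial rods: constant (x, y) through every section, inside the organ
    fiducials = []
    organ_all_z = organ.all(axis=0)
    ys, xs = np.nonzero(organ_all_z)
    if len(xs) < spec.n_fiducials:
        raise ValueError("organ too thin to host fiducial rods through all sections")
    order = rng.permutation(len(xs))
    chosen = []
    for idx in order:
        x, y = int(xs[idx]), int(ys[idx])
        if all((x - x2) ** 2 + (y - y2) ** 2 > 30**2 for x2, y2 in chosen):
            chosen.append((x, y))
        if len(chosen) == spec.n_fiducials:
            break
    if len(chosen) < spec.n_fiducials:
        chosen = [(int(xs[i]), int(ys[i])) for i in order[: spec.n_fiducials]]
    yy, xx = np.mgrid[0:ydim, 0:xdim]
    for x, y in chosen:
        rod = (xx - x) ** 2 + (yy - y) ** 2 <= 2.0**2
        volume[:, rod] = ROD_COLOR.astype(np.uint8)
        fiducials.append((float(x), float(y)))
    fiducials = np.asarray(fiducials)
    if return_labels:
        return volume, fiducials, labels
    return volume, fiducials


# ---------------------------------------------------------------------------
# Slicing and perturbation
# ---------------------------------------------------------------------------


def slice_volume(
    volume: np.ndarray,
    spec: PhantomSpec,
    fiducials: np.ndarray,
    interval_um: float | None = None,
    take_every_n: int = 1,
) -> tuple[SlideStack, GroundTruthRecord]:
    """Cut axial sections at a physical interval, optionally subsampled.

    ``take_every_n`` keeps one out of every n sections, multiplying the
    effective slice distance by n — the protocol used to simulate sparser
    sampling from a densely sectioned specimen. Landmarks are subsampled
    consistently with the slides.
    """
    interval = spec.slice_interval_um if interval_um is None else interval_um
    vz = spec.voxel_um[0]
    step_f = interval / vz
    step = int(round(step_f))
    if abs(step_f - step) > 1e-9 or step < 1:
        raise ValueError(f"interval ({interval} µm) must be a multiple of the z voxel size ({vz} µm)")
    z_indices = list(range(step // 2, volume.shape[0], step))[::take_every_n]
    if len(z_indices) < 2:
        raise ValueError(f"slicing would produce {len(z_indices)} slide(s); need at least 2")
    arrays = [volume[z] for z in z_indices]
    stack = SlideStack.from_arrays(
        arrays,
        spacing=spec.spacing,
        slice_interval=interval * take_every_n,
        ids=[f"section_{z:03d}" for z in z_indices],
    )
    gt = GroundTruthRecord.identity(len(arrays), [fiducials] * len(arrays))
    return stack, gt


def perturb_stack(
    stack: SlideStack,
    seed: int = 0,
    rotation_range: tuple[float, float] = (0.0, 360.0),
    max_translation: float = 15.0,
    flip_probability: float = 0.0,
    planted_flips: list[int] | None = None,
    stain_jitter: float = 0.05,
    gt: GroundTruthRecord | None = None,
) -> tuple[SlideStack, GroundTruthRecord]:
    """Apply independent per-slide rigid + color perturbations.

    Rotation is uniform in ``rotation_range`` (degrees, about the slide
    center), translation uniform in ``[-max_translation, max_translation]``
    per axis. A planted 180° flip (an extra half-turn, recorded separately)
    is applied with ``flip_probability``, or to the explicit
    ``planted_flips`` indices. Stain jitter applies a channel-wise affine
    color change to tissue pixels. Mirror flips are never generated. The
    returned record stores the exact planted transforms and the transformed
    landmark coordinates; composes with a prior record ``gt`` when the
    input stack was already transformed.
    """
    rng = np.random.default_rng(seed)
    if gt is None:
        gt = GroundTruthRecord.identity(stack.k, [np.empty((0, 2))] * stack.k)
    rotations, translations, flips, transforms, landmarks, arrays = [], [], [], [], [], []
    for i, slide in enumerate(stack):
        img = slide.read_level(0)
        h, w = img.shape[:2]
        theta = float(rng.uniform(*rotation_range))
        tx, ty = rng.uniform(-max_translation, max_translation, size=2)
        if planted_flips is not None:
            flip = i in planted_flips
        else:
            flip = bool(rng.uniform() < flip_probability)
        t = RigidTransform2D(
            theta=theta + (180.0 if flip else 0.0),
            tx=float(tx),
            ty=float(ty),
            center=((w - 1) / 2.0, (h - 1) / 2.0),
        )
        out = warp_image(img, t, background=255)
        if stain_jitter > 0:
            scale = rng.uniform(1 - stain_jitter, 1 + stain_jitter, size=3)
            offset = rng.uniform(-25.5 * stain_jitter, 25.5 * stain_jitter, size=3)
            tissue = out.astype(float) @ np.array([0.2125, 0.7154, 0.0721]) < 245
            vals = np.clip(out[tissue].astype(float) * scale + offset, 0, 255)
            out = out.copy()
            out[tissue] = vals.astype(np.uint8)
        arrays.append(out)
        rotations.append(theta)
        translations.append((float(tx), float(ty)))
        flips.append(flip)
        transforms.append(t.compose(gt.transforms[i]))
        landmarks.append(t.apply(gt.landmarks[i]) if len(gt.landmarks[i]) else gt.landmarks[i])
    new_stack = SlideStack.from_arrays(
        arrays, spacing=stack[0].spacing, slice_interval=stack.slice_interval,
        ids=[s.id for s in stack],
    )
    record = GroundTruthRecord(
        rotations=np.asarray(rotations) + gt.rotations,
        translations=np.asarray(translations) + gt.translations,
        flips=np.asarray(flips) ^ gt.flips,
        transforms=transforms,
        landmarks=landmarks,
    )
    return new_stack, record


def make_phantom_stack(
    seed: int = 0,
    spec: PhantomSpec | None = None,
    take_every_n: int = 1,
    interval_um: float | None = None,
    rotation_range: tuple[float, float] = (0.0, 360.0),
    max_translation: float = 15.0,
    flip_probability: float = 0.0,
    planted_flips: list[int] | None = None,
    stain_jitter: float = 0.05,
):
    """Generate → slice → perturb in one call.

    Returns ``(stack, ground_truth, spec)``. The perturbation seed is
    derived from ``seed`` so one integer reproduces the whole case.
    """
    if spec is None:
        spec = PhantomSpec(seed=seed)
    volume, fiducials = generate_phantom(spec)
    stack, gt = slice_volume(volume, spec, fiducials, interval_um=interval_um,
                             take_every_n=take_every_n)
    stack, gt = perturb_stack(
        stack,
        seed=seed + 1,
        rotation_range=rotation_range,
        max_translation=max_translation,
        flip_probability=flip_probability,
        planted_flips=planted_flips,
        stain_jitter=stain_jitter,
        gt=gt,
    )
    return stack, gt, spec


# ---------------------------------------------------------------------------
# Scoring recovered alignments against the planted geometry
# ---------------------------------------------------------------------------


def ideal_alignment(gt: GroundTruthRecord, reference: int) -> list[RigidTransform2D]:
    """Transforms a perfect reconstruction would recover.

    The planted ``G_i`` maps the common section frame into slide ``i``; a
    perfect alignment maps slide ``i`` back through the common frame into
    the reference slide: ``A_i* = G_r ∘ G_i^{-1}``.
    """
    g_r = gt.transforms[reference]
    return [g_r.compose(g.inverse()) for g in gt.transforms]


def recovery_errors(
    transforms: list[RigidTransform2D],
    gt: GroundTruthRecord,
    reference: int,
    frame_size: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-slide rotation (deg) and translation (px) recovery errors.

    Translation error is the displacement between recovered and ideal
    mapping of the frame center, after removing the rotation error's
    contribution is *not* attempted — the displacement at the center is the
    quantity that moves tissue, so it is what is scored.
    """
    from .transform import wrap_angle

    ideal = ideal_alignment(gt, reference)
    center = np.array([(frame_size - 1) / 2.0] * 2)
    rot_err, trans_err = [], []
    for rec, ide in zip(transforms, ideal):
        rot_err.append(wrap_angle(rec.theta - ide.theta))
        trans_err.append(float(np.linalg.norm(rec.apply(center) - ide.apply(center))))
    return np.asarray(rot_err), np.asarray(trans_err)
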