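"""Reconstruction-quality metrics.

Three complementary measures, because no single number captures the success
of a 3-D reconstruction:

* **Orientation accuracy** — a case counts as successfully reconstructed
  when every slide's rotation deviates at most 15° (circular, signed) from
  its ground-truth rotation relative to the reference slide.
* **Overlap** — for each of the k−1 adjacent pairs, the intersection area
  divided by the *smaller* slide's area (real size differences between
  adjacent sections are anatomically plausible and must not be penalized),
  averaged over pairs:  O = 1/(k−1) · Σ |Aₙ ∩ Aₙ₊₁| / min(|Aₙ|, |Aₙ₊₁|).
* **Target registration error (TRE)** — per adjacent pair the *median*
  Euclidean distance over its matched point pairs (median for robustness to
  outlier matches), averaged over the k−1 pairs; reported in pixels and mm.

The estimated TRE re-detects feature matches on an already-registered stack
without modifying any transform, so it can score reconstructions produced
by this package or externally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FeatureBackend, InsufficientMatchesError, MatchSet, SlideView, dense_match
from .register import NoConsensusError, estimate_rigid
from .transform import wrap_angle


@dataclass
class OrientationReport:
    deviations: np.ndarray  # signed degrees in (-180, 180], reference = 0
    threshold: float
    slide_pass: np.ndarray
    case_accurate: bool

    def to_dict(self) -> dict:
        return {
            "deviations_deg": self.deviations.tolist(),
            "threshold_deg": self.threshold,
            "slide_pass": self.slide_pass.tolist(),
            "case_accurate": bool(self.case_accurate),
        }


@dataclass
class OverlapReport:
    pair_overlaps: np.ndarray  # (k-1,) in [0, 1]
    mean_overlap: float
    flagged_pairs: list

    def to_dict(self) -> dict:
        return {
            "pair_overlaps": self.pair_overlaps.tolist(),
            "mean_overlap": self.mean_overlap,
            "flagged_pairs": self.flagged_pairs,
        }


@dataclass
class TREReport:
    pair_medians: np.ndarray  # (n_pairs,) pixels
    tre: float  # mean of pair medians, pixels
    tre_mm: float
    spacing: float  # µm/pixel used for the mm conversion
    skipped_pairs: list = None

    def to_dict(self) -> dict:
        return {
            "pair_medians_px": self.pair_medians.tolist(),
            "tre_px": self.tre,
            "tre_mm": self.tre_mm,
            "spacing_um_per_px": self.spacing,
            "skipped_pairs": self.skipped_pairs or [],
        }


def orientation_accuracy(
    pred: np.ndarray,
    truth: np.ndarray,
    threshold: float = 15.0,
    reference_index: int | None = None,
) -> OrientationReport:
    """Per-slide rotation deviation from ground truth, relative to the reference.

    Deviations are computed on the circle (wrap-aware), then re-expressed
    relative to the reference slide so the reference's deviation is exactly
    zero. The case passes when all slides deviate at most ``threshold``
    degrees. Raising the threshold can never turn a passing case failing.
    """
    pred, truth = np.asarray(pred, dtype=float), np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    if not (np.all(np.isfinite(pred)) and np.all(np.isfinite(truth))):
        raise ValueError("angles must be finite")
    r = (len(pred) - 1) // 2 if reference_index is None else reference_index
    raw = wrap_angle(pred - truth)
    dev = wrap_angle(raw - raw[r])
    ok = np.abs(dev) <= threshold
    return OrientationReport(dev, threshold, ok, bool(ok.all()))


def dataset_accuracy(reports: list[OrientationReport]) -> float:
    """Fraction of cases where every slide passed the orientation heuristic."""
    if not reports:
        raise ValueError("no cases")
    return float(np.mean([r.case_accurate for r in reports]))


def overlap(masks: list[np.ndarray]) -> OverlapReport:
    """Adjacent-pair overlap of registered tissue masks (see module docstring)."""
    if len(masks) < 2:
        raise ValueError("need k >= 2 masks")
    ms = [np.asarray(m) > 0 for m in masks]
    if len({m.shape for m in ms}) != 1:
        raise ValueError("masks must share the registered frame")
    vals, flagged = [], []
    for n, (a, b) in enumerate(zip(ms[:-1], ms[1:])):
        area_a, area_b = int(a.sum()), int(b.sum())
        if min(area_a, area_b) == 0:
            vals.append(0.0)
            flagged.append(n)
            continue
        vals.append(float(np.logical_and(a, b).sum() / min(area_a, area_b)))
    arr = np.asarray(vals)
    return OverlapReport(arr, float(arr.mean()), flagged)


def tre(
    pairs: list[MatchSet | tuple[np.ndarray, np.ndarray]],
    spacing: float,
    inliers_only: bool = False,
) -> TREReport:
    """Mean over adjacent pairs of the per-pair median match distance."""
    if not pairs:
        raise ValueError("no pairs")
    medians = []
    for p in pairs:
        if isinstance(p, MatchSet):
            sel = p.inlier if (inliers_only and p.inlier.any()) else np.ones(p.m, dtype=bool)
            pa, pb = p.points_a[sel], p.points_b[sel]
        else:
            pa, pb = np.atleast_2d(np.asarray(p[0])), np.atleast_2d(np.asarray(p[1]))
        if len(pa) == 0:
            raise ValueError("a pair has no correspondences; cannot take a median")
        medians.append(float(np.median(np.linalg.norm(pa - pb, axis=1))))
    arr = np.asarray(medians)
    mean_px = float(arr.mean())
    return TREReport(arr, mean_px, mean_px * spacing / 1000.0, spacing)


def landmark_tre(landmarks: list[np.ndarray], spacing: float) -> TREReport:
    """TRE from per-slide landmark coordinates already in a common frame."""
    pairs = [(landmarks[n], landmarks[n + 1]) for n in range(len(landmarks) - 1)]
    return tre(pairs, spacing)


def estimated_tre(
    images: list[np.ndarray],
    masks: list[np.ndarray],
    backend: FeatureBackend,
    spacing: float,
    seed: int = 0,
    poses=None,
    ransac_threshold: float = 3.0,
    ransac_iterations: int = 1000,
) -> TREReport:
    """Feature-estimated TRE of an already-registered stack.

    Dense matches are re-detected on each adjacent pair of the registered
    rasters; RANSAC selects the inlier correspondences (the same filtering
    used during reconstruction) but the estimated transform is *not*
    applied — the median inlier distance directly measures the residual
    misalignment. A pair whose matches admit no rigid consensus still
    contributes the median over its *unfiltered* matches (the residual
    misalignment there is real; only the inlier selection is unavailable);
    pairs with too few matches altogether are skipped and flagged.
    Read-only: no input is modified.
    """
    from .transform import RigidTransform2D

    k = len(images)
    if poses is None:
        poses = [RigidTransform2D()] * k
    rng = np.random.default_rng(seed)
    match_pairs, skipped = [], []
    for n in range(k - 1):
        pair_seed = int(rng.integers(0, 2**31 - 1))
        va = SlideView(images[n], masks[n], index=n, pose=poses[n])
        vb = SlideView(images[n + 1], masks[n + 1], index=n + 1, pose=poses[n + 1])
        try:
            matches = dense_match(va, vb, backend, seed=pair_seed)
        except InsufficientMatchesError:
            skipped.append(n)
            continue
        try:
            _, matches = estimate_rigid(matches, seed=pair_seed, threshold=ransac_threshold,
                                        iterations=ransac_iterations)
        except NoConsensusError:
            matches.inlier[:] = False  # fall through to the unfiltered median
        match_pairs.append(matches)
    if not match_pairs:
        raise ValueError("no pair produced sufficient matches")
    report = tre(match_pairs, spacing, inliers_only=True)
    report.skipped_pairs = skipped
    return report
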