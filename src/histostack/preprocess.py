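"""Stack harmonization before alignment.

Four steps, applied in order: (1) tissue foreground masking by Otsu
thresholding of the luminance with morphological cleanup, (2) Reinhard-style
stain normalization in the decorrelated lαβ color space toward the
element-wise median of the per-slide channel statistics, (3) resampling of
every slide to one common spacing chosen to bring the largest slide closest
to ``target_pixels`` on its longer side, and (4) padding to a shared square
canvas. The full RGB color space is preserved throughout — slides are never
collapsed to grayscale — and all background pixels are set to a constant so
scanner noise and minor artefacts outside the tissue cannot influence
feature matching downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import morphology
from skimage.color import rgb2gray
from skimage.transform import resize

from .stack_io import SlideImage, SlideStack

BACKGROUND_WHITE = (255, 255, 255)


# ---------------------------------------------------------------------------
# Tissue masking
# ---------------------------------------------------------------------------


@dataclass
class TissueMask:
    """Binary foreground raster aligned to one slide at one resolution."""

    mask: np.ndarray  # bool (H, W)
    coverage: float  # foreground fraction in [0, 1]
    degenerate: bool = False  # constant-intensity input, mask unusable

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        assert 0.0 <= self.coverage <= 1.0


def otsu_threshold(hist: np.ndarray) -> int:
    """Otsu's threshold on a 256-bin 8-bit histogram.

    Returns the gray level ``t`` maximizing the between-class variance of
    the split ``{0..t} | {t+1..255}`` (first maximum on ties).
    """
    hist = np.asarray(hist, dtype=float)
    if hist.shape != (256,):
        raise ValueError("expected a 256-bin histogram")
    total = hist.sum()
    if total == 0:
        raise ValueError("empty histogram")
    levels = np.arange(256)
    w0 = np.cumsum(hist)
    w1 = total - w0
    cum = np.cumsum(hist * levels)
    mu0 = np.where(w0 > 0, cum / np.maximum(w0, 1), 0.0)
    mu1 = np.where(w1 > 0, (cum[-1] - cum) / np.maximum(w1, 1), 0.0)
    var_between = w0 * w1 * (mu0 - mu1) ** 2
    var_between[(w0 == 0) | (w1 == 0)] = -1.0
    return int(np.argmax(var_between))


def compute_tissue_mask(
    image: np.ndarray,
    cleanup: bool = True,
    cleanup_radius: int = 2,
    min_object_fraction: float = 1e-3,
) -> TissueMask:
    """Otsu-threshold the luminance of an RGB raster into tissue/background.

    Tissue is the dark class (stained tissue on a bright glass background).
    Cleanup applies morphological closing then opening with a disk of
    ``cleanup_radius`` pixels and discards connected components smaller than
    ``min_object_fraction`` of the total foreground area, erasing background
    specks and minor artefacts. A constant-intensity image yields an
    all-background mask flagged degenerate.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    gray = np.clip(np.rint(rgb2gray(image) * 255), 0, 255).astype(np.uint8) if image.ndim == 3 else image
    if gray.max() == gray.min():
        warnings.warn("constant-intensity image: degenerate histogram, all-background mask")
        return TissueMask(np.zeros(gray.shape, dtype=bool), 0.0, degenerate=True)
    hist = np.bincount(gray.ravel(), minlength=256)[:256]
    t = otsu_threshold(hist)
    mask = gray <= t
    if cleanup and mask.any():
        footprint = morphology.disk(cleanup_radius)
        mask = morphology.closing(mask, footprint)
        mask = morphology.opening(mask, footprint)
        if mask.any():
            min_size = max(1, int(min_object_fraction * mask.sum()))
            mask = morphology.remove_small_objects(mask, max_size=min_size - 1)
    return TissueMask(mask, float(mask.mean()))


# ---------------------------------------------------------------------------
# Reinhard-style stain normalization in lαβ
# ---------------------------------------------------------------------------

# Ruderman's RGB -> LMS -> lαβ decorrelated color space.
_RGB2LMS = np.array(
    [[0.3811, 0.5783, 0.0402], [0.1967, 0.7244, 0.0782], [0.0241, 0.1288, 0.8444]]
)
_LMS2RGB = np.linalg.inv(_RGB2LMS)
_LMS2LAB = np.diag([1 / np.sqrt(3), 1 / np.sqrt(6), 1 / np.sqrt(2)]) @ np.array(
    [[1, 1, 1], [1, 1, -2], [1, -1, 0]], dtype=float
)
_LAB2LMS = np.linalg.inv(_LMS2LAB)


def rgb_to_lab(rgb: np.ndarray) -> np.ndarray:
    lms = np.clip(rgb.astype(float) / 255.0, 0, 1) @ _RGB2LMS.T
    return np.log10(np.maximum(lms, 1e-6)) @ _LMS2LAB.T


def lab_to_rgb(lab: np.ndarray) -> np.ndarray:
    lms = 10.0 ** (lab @ _LAB2LMS.T)
    rgb = lms @ _LMS2RGB.T
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


@dataclass
class ColorStats:
    """Per-slide lαβ foreground statistics and their stack-wide median."""

    means: np.ndarray  # (k, 3)
    stds: np.ndarray  # (k, 3)
    median_mean: np.ndarray = field(default=None)
    median_std: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.median_mean is None:
            self.median_mean = np.median(self.means, axis=0)
        if self.median_std is None:
            self.median_std = np.median(self.stds, axis=0)


def normalize_stains(
    images: list[np.ndarray], masks: list[TissueMask]
) -> tuple[list[np.ndarray], ColorStats]:
    """Map each slide's foreground color statistics to the stack median.

    Statistics (per-channel mean and standard deviation in lαβ) are computed
    over foreground pixels only, so glass background cannot bias the match.
    Each foreground pixel is shifted and scaled channel-wise onto the
    element-wise median of the per-slide statistics; background is left
    untouched. Slides with a degenerate mask or zero channel variance pass
    through unmodified with a warning.
    """
    if len(images) < 2:
        raise ValueError("stain normalization needs at least 2 slides")
    labs, means, stds, usable = [], [], [], []
    for img, tm in zip(images, masks):
        lab = rgb_to_lab(img)
        fg = lab[tm.mask]
        ok = not tm.degenerate and len(fg) > 1
        mean = fg.mean(axis=0) if ok else np.zeros(3)
        std = fg.std(axis=0) if ok else np.zeros(3)
        if ok and np.any(std <= 1e-12):
            ok = False
        labs.append(lab)
        means.append(mean)
        stds.append(std)
        usable.append(ok)
    means, stds = np.asarray(means), np.asarray(stds)
    if not any(usable):
        raise ValueError("no slide has a usable foreground for stain normalization")
    stats = ColorStats(means, stds, np.median(means[usable], axis=0), np.median(stds[usable], axis=0))
    out = []
    for img, tm, lab, mean, std, ok in zip(images, masks, labs, means, stds, usable):
        if not ok:
            warnings.warn("degenerate slide passed through stain normalization unmodified")
            out.append(img.copy())
            continue
        lab = lab.copy()
        lab[tm.mask] = (lab[tm.mask] - mean) * (stats.median_std / std) + stats.median_mean
        res = img.copy()
        res[tm.mask] = lab_to_rgb(lab[tm.mask])
        out.append(res)
    return out, stats


# ---------------------------------------------------------------------------
# Common spacing and the processed stack
# ---------------------------------------------------------------------------


def select_common_spacing(stack: SlideStack, target_pixels: int = 2000) -> float:
    """One spacing (µm/pixel) for the whole stack.

    Chosen so the largest slide's longer side lands closest to
    ``target_pixels`` (e.g. 2000 px), from the candidate set formed by the
    slide's pyramid ladder extended with integer multiples of its level-0
    spacing (integer-factor resampling). Ties break toward the coarser
    spacing. Deterministic.
    """
    largest = max(stack, key=lambda s: max(s.levels[0][1], s.levels[0][2]) * s.spacing)
    physical_long = max(largest.levels[0][1], largest.levels[0][2]) * largest.spacing
    candidates = {largest.spacing * d for d, _, _ in largest.levels}
    n_max = max(1, int(np.ceil(2.0 * physical_long / (target_pixels * largest.spacing))))
    candidates.update(largest.spacing * n for n in range(1, n_max + 1))

    def cost(s: float) -> tuple[float, float]:
        return (abs(physical_long / s - target_pixels), -s)  # tie -> coarser

    return float(min(candidates, key=cost))


def _resample_slide(slide: SlideImage, common_spacing: float) -> np.ndarray:
    level = slide.best_level_for_spacing(common_spacing)
    img = slide.read_level(level)
    factor = slide.level_spacing(level) / common_spacing
    if abs(factor - 1.0) < 1e-9:
        return img.copy()
    out_shape = (max(1, round(img.shape[0] * factor)), max(1, round(img.shape[1] * factor)))
    res = resize(img.astype(float), out_shape + (3,), order=1, anti_aliasing=factor < 1, preserve_range=True)
    return np.clip(np.rint(res), 0, 255).astype(np.uint8)


@dataclass
class ProcessedStack:
    """Harmonized stack: all slides D x D at one spacing, masked and padded.

    ``pad_offsets[i]`` is the (dx, dy) of slide i's resampled content within
    the padded frame; together with ``scales[i]`` (level-0 px -> processed
    px) it lets any transform estimated in the processed frame be composed
    back to the slide's native level-0 frame.
    """

    images: list[np.ndarray]
    masks: list[TissueMask]
    common_spacing: float
    pad_offsets: list[tuple[int, int]]
    scales: list[float]
    slide_ids: list[str]
    slice_interval: float
    color_stats: ColorStats | None = None
    background: tuple[int, int, int] = BACKGROUND_WHITE

    @property
    def k(self) -> int:
        return len(self.images)

    @property
    def frame_size(self) -> int:
        return self.images[0].shape[0]

    def processed_to_level0(self, i: int, points: np.ndarray) -> np.ndarray:
        """Map processed-frame points of slide ``i`` back to its level-0 frame."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        dx, dy = self.pad_offsets[i]
        out = (pts - [dx, dy]) / self.scales[i]
        return out[0] if np.ndim(points) == 1 else out

    def level0_to_processed(self, i: int, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        dx, dy = self.pad_offsets[i]
        out = pts * self.scales[i] + [dx, dy]
        return out[0] if np.ndim(points) == 1 else out


def build_processed_stack(
    stack: SlideStack,
    target_pixels: int = 2000,
    background: tuple[int, int, int] = BACKGROUND_WHITE,
    normalize: bool = True,
    cleanup_radius: int = 2,
) -> ProcessedStack:
    """Run the full preprocessing chain on a stack.

    Masking happens at the common processing resolution; the masked
    background is replaced with the configured constant (white by default,
    matching glass), stains are normalized to the stack median, and every
    slide is centered on a shared square canvas whose side is the largest
    resampled slide extent. Padding never clips foreground.
    """
    common = select_common_spacing(stack, target_pixels)
    images, masks = [], []
    for slide in stack:
        img = _resample_slide(slide, common)
        tm = compute_tissue_mask(img, cleanup_radius=cleanup_radius)
        img = img.copy()
        img[~tm.mask] = background
        images.append(img)
        masks.append(tm)
    stats = None
    if normalize:
        images, stats = normalize_stains(images, masks)
    side = max(max(im.shape[0], im.shape[1]) for im in images)
    padded_imgs, padded_masks, offsets = [], [], []
    for img, tm in zip(images, masks):
        h, w = img.shape[:2]
        dy, dx = (side - h) // 2, (side - w) // 2
        canvas = np.empty((side, side, 3), dtype=np.uint8)
        canvas[:] = background
        canvas[dy : dy + h, dx : dx + w] = img
        mcanvas = np.zeros((side, side), dtype=bool)
        mcanvas[dy : dy + h, dx : dx + w] = tm.mask
        padded_imgs.append(canvas)
        padded_masks.append(TissueMask(mcanvas, float(mcanvas.mean()), tm.degenerate))
        offsets.append((dx, dy))
    return ProcessedStack(
        images=padded_imgs,
        masks=padded_masks,
        common_spacing=common,
        pad_offsets=offsets,
        scales=[s.spacing / common for s in stack],
        slide_ids=[s.id for s in stack],
        slice_interval=stack.slice_interval,
        color_stats=stats,
        background=background,
    )
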