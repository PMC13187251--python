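"""Section-image I/O and stack assembly.

Reads pyramidal TIFFs (each reduced-resolution level stored as a page) and
plain RGB rasters (PNG / single-page TIFF) with a user-declared physical
pixel spacing, writes tiled pyramidal TIFFs from either a full array or a
bounded-memory tile stream, and assembles ordered :class:`SlideStack`
objects ready for reconstruction.

The level-0 frame is canonical: all transforms elsewhere in the package are
stored in level-0 pixel units and rescaled per level. Pixel spacing is
µm/pixel at level 0. Written TIFFs carry their spacing and level ladder in a
JSON ``ImageDescription`` tag so round-trips need no sidecar file.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import tifffile

try:  # optional, only needed for PNG inputs
    import imageio.v3 as iio
except ImportError:  # pragma: no cover
    iio = None

DESCRIPTION_KEY = "histostack"


class StackIOError(IOError):
    """Unreadable, truncated, or unwritable slide file."""


class StackConfigError(ValueError):
    """Invalid stack configuration (missing spacing, too few slides, ...)."""


# ---------------------------------------------------------------------------
# Slide containers
# ---------------------------------------------------------------------------


@dataclass
class SlideImage:
    """One section image with its resolution ladder.

    ``levels`` lists ``(downsample, width, height)`` per pyramid level with
    strictly increasing downsample factors starting at 1. Pixels are either
    held in memory (``arrays``) or read lazily from ``path``.
    """

    id: str
    spacing: float  # µm/pixel at level 0
    levels: list[tuple[float, int, int]]
    z_index: int = 0
    path: str | None = None
    arrays: list[np.ndarray] | None = None
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise StackConfigError(f"slide {self.id!r}: spacing must be > 0")
        if not self.levels:
            raise StackConfigError(f"slide {self.id!r}: empty level ladder")
        downs = [lv[0] for lv in self.levels]
        if downs[0] != 1 or any(b <= a for a, b in zip(downs, downs[1:])):
            raise StackConfigError(
                f"slide {self.id!r}: downsample factors must be strictly increasing from 1, got {downs}"
            )
        for d, w, h in self.levels:
            if w < 1 or h < 1:
                raise StackConfigError(f"slide {self.id!r}: degenerate level {(d, w, h)}")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def level_spacing(self, level: int) -> float:
        return self.spacing * self.levels[level][0]

    def read_level(self, level: int = 0) -> np.ndarray:
        """Full RGB raster of one pyramid level as ``(H, W, 3)`` uint8."""
        if self.arrays is not None:
            return self.arrays[level]
        if level not in self._cache:
            try:
                arr = tifffile.imread(self.path, key=level)
            except Exception as exc:  # noqa: BLE001 - normalize reader errors
                raise StackIOError(f"cannot read level {level} of {self.path}: {exc}") from exc
            self._cache[level] = _as_rgb(arr, self.id)
        return self._cache[level]

    def read_region(self, level: int, x0: int, y0: int, w: int, h: int) -> np.ndarray:
        full = self.read_level(level)
        return full[y0 : y0 + h, x0 : x0 + w]

    def best_level_for_spacing(self, target_spacing: float) -> int:
        """Finest level whose spacing does not exceed the target."""
        best = 0
        for i, (d, _, _) in enumerate(self.levels):
            if self.spacing * d <= target_spacing + 1e-9:
                best = i
        return best

    @classmethod
    def from_array(cls, pixels: np.ndarray, spacing: float, id: str = "slide", z_index: int = 0) -> "SlideImage":
        pixels = _as_rgb(np.asarray(pixels), id)
        h, w = pixels.shape[:2]
        return cls(id=id, spacing=spacing, levels=[(1.0, w, h)], z_index=z_index, arrays=[pixels])


@dataclass
class SlideStack:
    """Ordered stack of sections with a common physical slice interval (µm)."""

    slides: list[SlideImage]
    slice_interval: float

    def __post_init__(self) -> None:
        if len(self.slides) < 2:
            raise StackConfigError(f"a stack needs at least 2 slides, got {len(self.slides)}")
        if self.slice_interval <= 0:
            raise StackConfigError("slice_interval must be > 0")
        zs = [s.z_index for s in self.slides]
        if zs != list(range(zs[0], zs[0] + len(zs))):
            raise StackConfigError(f"z indices must be strictly increasing and gap-free, got {zs}")

    @property
    def k(self) -> int:
        return len(self.slides)

    def __iter__(self) -> Iterator[SlideImage]:
        return iter(self.slides)

    def __getitem__(self, i: int) -> SlideImage:
        return self.slides[i]

    @classmethod
    def from_arrays(
        cls,
        arrays: Sequence[np.ndarray],
        spacing: float,
        slice_interval: float,
        ids: Sequence[str] | None = None,
    ) -> "SlideStack":
        if ids is None:
            ids = [f"slide_{i:03d}" for i in range(len(arrays))]
        slides = [
            SlideImage.from_array(a, spacing, id=str(sid), z_index=i)
            for i, (a, sid) in enumerate(zip(arrays, ids))
        ]
        return cls(slides=slides, slice_interval=slice_interval)


def _as_rgb(arr: np.ndarray, slide_id: str) -> np.ndarray:
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[..., :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise StackConfigError(f"slide {slide_id!r}: expected an RGB raster, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    return arr


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------


def read_slide(path: str, spacing: float | None = None, id: str | None = None, z_index: int = 0) -> SlideImage:
    """Read a pyramidal TIFF or a plain RGB image into a :class:`SlideImage`.

    TIFFs written by :func:`write_slide` carry their spacing and level
    ladder in the ``ImageDescription`` tag; other inputs need ``spacing``
    (µm/pixel) declared by the caller.
    """
    if not os.path.exists(path):
        raise StackIOError(f"no such file: {path}")
    slide_id = id or os.path.splitext(os.path.basename(path))[0]
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        try:
            with tifffile.TiffFile(path) as tif:
                meta = _read_description(tif)
                pages = tif.pages
                levels = []
                base_w = pages[0].imagewidth
                for page in pages:
                    w, h = page.imagewidth, page.imagelength
                    levels.append((base_w / w, w, h))
        except StackIOError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StackIOError(f"cannot read TIFF {path}: {exc}") from exc
        file_spacing = meta.get("spacing_um")
        spacing = spacing if spacing is not None else file_spacing
        if spacing is None:
            raise StackConfigError(f"{path}: no spacing stored in file and none declared")
        return SlideImage(id=slide_id, spacing=float(spacing), levels=levels, z_index=z_index, path=path)
    # plain raster (PNG, ...)
    if spacing is None:
        raise StackConfigError(f"{path}: plain images need a declared spacing (µm/pixel)")
    if iio is None:  # pragma: no cover
        raise StackIOError("imageio is required to read non-TIFF images")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001
        raise StackIOError(f"cannot read image {path}: {exc}") from exc
    return SlideImage.from_array(arr, float(spacing), id=slide_id, z_index=z_index)


def _read_description(tif: tifffile.TiffFile) -> dict:
    desc = tif.pages[0].description or ""
    try:
        meta = json.loads(desc)
        if isinstance(meta, dict) and DESCRIPTION_KEY in meta:
            return meta[DESCRIPTION_KEY]
    except json.JSONDecodeError:
        pass
    return {}


def load_stack(
    paths: Sequence[str],
    slice_interval: float,
    spacing: float | None = None,
) -> SlideStack:
    """Read an ordered list of section files into a :class:`SlideStack`.

    The list order defines the z order; all slides must be RGB.
    """
    if len(paths) < 2:
        raise StackConfigError(f"need at least 2 slide paths, got {len(paths)}")
    slides = []
    for i, p in enumerate(paths):
        slide = read_slide(p, spacing=spacing, z_index=i)
        slide.read_level(slide.n_levels - 1)  # validates color model on the smallest level
        slides.append(slide)
    return SlideStack(slides=slides, slice_interval=slice_interval)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


class TileStream:
    """Row-major tile stream with live-tile accounting.

    Wraps ``((x0, y0), tile)`` pairs (as produced by
    :func:`histostack.transform.warp_tiled`) and hands plain tile arrays to
    the TIFF writer one at a time, verifying that the stream covers the
    output extent exactly once in row-major order. ``max_live_tiles``
    records the peak number of tiles held simultaneously, which is the
    quantity bounding memory use of a streamed write.
    """

    def __init__(self, tiles: Iterable, shape: tuple[int, int, int], tile_size: int):
        self._tiles = iter(tiles)
        self.shape = shape
        self.tile_size = tile_size
        h, w = shape[:2]
        self.expected = -(-w // tile_size) * -(-h // tile_size)
        self.consumed = 0
        self.live_tiles = 0
        self.max_live_tiles = 0

    def __iter__(self) -> Iterator[np.ndarray]:
        ts = self.tile_size
        h, w = self.shape[:2]
        positions = [(x0, y0) for y0 in range(0, h, ts) for x0 in range(0, w, ts)]
        for x0, y0 in positions:
            try:
                item = next(self._tiles)
            except StopIteration:
                raise StackIOError(
                    f"tile stream ended after {self.consumed}/{self.expected} tiles"
                ) from None
            pos, tile = item if isinstance(item, tuple) and len(item) == 2 else ((x0, y0), item)
            if tuple(pos) != (x0, y0):
                raise StackIOError(f"tile stream out of order: expected {(x0, y0)}, got {tuple(pos)}")
            self.live_tiles += 1
            self.max_live_tiles = max(self.max_live_tiles, self.live_tiles)
            self.consumed += 1
            # TIFF tile payloads are full tile-sized; pad edge tiles.
            th, tw = tile.shape[:2]
            if th != ts or tw != ts:
                padded = np.zeros((ts, ts) + tile.shape[2:], dtype=tile.dtype)
                padded[:th, :tw] = tile
                tile = padded
            yield tile
            self.live_tiles -= 1

    def finish(self) -> None:
        """Verify the stream covered the extent exactly once."""
        if self.consumed != self.expected:
            raise StackIOError(f"tile stream covered {self.consumed}/{self.expected} tiles")
        try:
            next(self._tiles)
        except StopIteration:
            return
        raise StackIOError("tile stream yielded more tiles than the output extent")


def _downsample2(arr: np.ndarray) -> np.ndarray:
    """2x2 block-mean reduction with edge replication for odd extents."""
    h, w = arr.shape[:2]
    if h % 2:
        arr = np.concatenate([arr, arr[-1:]], axis=0)
    if w % 2:
        arr = np.concatenate([arr, arr[:, -1:]], axis=1)
    h2, w2 = arr.shape[0] // 2, arr.shape[1] // 2
    a = arr.reshape(h2, 2, w2, 2, -1).astype(float).mean(axis=(1, 3))
    return np.clip(np.rint(a), 0, 255).astype(np.uint8).reshape(h2, w2, *arr.shape[2:])


def write_slide(
    image: np.ndarray | Iterable,
    path: str,
    spacing: float = 1.0,
    tile_size: int = 256,
    pyramid_levels: int = 1,
    compression: str = "zlib",
    shape: tuple[int, int, int] | None = None,
    id: str = "slide",
) -> str:
    """Write a tiled pyramidal TIFF.

    ``image`` is either a full ``(H, W, 3)`` uint8 array or a row-major tile
    stream (``shape`` then required); streamed writes hold only a constant
    number of tiles of the full-resolution level in memory at once.
    Reduced-resolution levels are appended as additional pages by repeated
    2x2 block-mean reduction. Default codec is lossless deflate so
    round-trips are bit-exact; pass ``compression="jpeg"`` to trade that for
    size.

    Returns the path written.
    """
    if isinstance(image, np.ndarray):
        arr = _as_rgb(image, id)
        shape = arr.shape
        stream = None
    else:
        if shape is None:
            raise StackConfigError("streamed write_slide needs an explicit shape")
        stream = TileStream(image, shape, tile_size)
    h, w = shape[:2]
    meta = {
        DESCRIPTION_KEY: {"spacing_um": float(spacing), "id": id, "pyramid_levels": int(pyramid_levels)}
    }
    kwargs = dict(tile=(tile_size, tile_size), compression=compression, photometric="rgb")
    try:
        with tifffile.TiffWriter(path, bigtiff=w * h * 3 > 2**31) as tw:
            if stream is None:
                tw.write(arr, description=json.dumps(meta), **kwargs)
            else:
                tw.write(
                    iter(stream),
                    shape=shape,
                    dtype=np.uint8,
                    description=json.dumps(meta),
                    **kwargs,
                )
        # Reduced levels: each built from the previous page. One level is
        # resident at a time; the streamed level-0 path above is the
        # memory-critical one for gigapixel inputs.
        prev = None
        for _ in range(1, pyramid_levels):
            if prev is None:
                prev = tifffile.imread(path, key=0)
            prev = _downsample2(prev)
            with tifffile.TiffWriter(path, append=True) as tw:
                tw.write(prev, **kwargs)
    except StackIOError:
        raise
    except OSError as exc:
        raise StackIOError(f"cannot write {path}: {exc}") from exc
    if stream is not None:
        stream.finish()
    return path


# ---------------------------------------------------------------------------
# Landmark CSV (slide_id,x,y in level-0 pixels)
# ---------------------------------------------------------------------------


def write_landmarks(landmarks: dict[str, np.ndarray], path: str) -> str:
    with open(path, "w") as fh:
        fh.write("slide_id,x,y\n")
        for sid, pts in landmarks.items():
            for x, y in np.atleast_2d(pts):
                fh.write(f"{sid},{x:.6g},{y:.6g}\n")
    return path


def read_landmarks(path: str) -> dict[str, np.ndarray]:
    out: dict[str, list] = {}
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        if header[:3] != ["slide_id", "x", "y"]:
            raise StackConfigError(f"{path}: expected header slide_id,x,y")
        for line in fh:
            if not line.strip():
                continue
            sid, x, y = line.strip().split(",")[:3]
            out.setdefault(sid, []).append((float(x), float(y)))
    return {sid: np.asarray(pts, dtype=float) for sid, pts in out.items()}
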