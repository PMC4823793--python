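"""Image loading, preprocessing, tissue masking and whole-slide tiling.

Bright-field DISH images arrive as 8-bit RGB TIFF/PNG/JPEG.  Single tissue
cores are resized to a fixed working size (default 4096 x 4096, bicubic) so
that downstream pixel-unit parameters mean the same thing on every core;
whole slides are kept at native resolution and processed as 4096 x 4096
tiles whose detections are merged back into slide coordinates.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import FormatError, ParameterError
from .points import SignalPoint

DEFAULT_TARGET_SIZE = 4096
DEFAULT_TILE_SIZE = 4096
DEFAULT_TILE_OVERLAP = 64


@dataclass
class RasterImage:
    """8-bit RGB raster with optional physical pixel size.

    ``pixels`` has shape (height, width, 3), dtype uint8.
    """

    pixels: np.ndarray
    microns_per_pixel: float | None = None

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim == 2:
            px = np.stack([px] * 3, axis=-1)
        if px.ndim != 3 or px.shape[2] < 3:
            raise FormatError(f"expected an RGB raster, got shape {px.shape}")
        if px.shape[2] > 3:
            px = px[:, :, :3]  # drop alpha
        if px.dtype != np.uint8:
            px = np.clip(np.round(np.asarray(px, dtype=float)), 0, 255).astype(np.uint8)
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise FormatError("empty image")
        if self.microns_per_pixel is not None and self.microns_per_pixel <= 0:
            raise ParameterError("microns_per_pixel must be > 0")
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]

    def as_float(self) -> np.ndarray:
        """(H, W, 3) float32 in [0, 1]."""
        return self.pixels.astype(np.float32) / 255.0

    def crop(self, x0: int, y0: int, x1: int, y1: int) -> "RasterImage":
        return RasterImage(self.pixels[y0:y1, x0:x1].copy(), self.microns_per_pixel)


@dataclass
class TissueMask:
    """Binary mask marking tissue (True) vs background, same shape as its image."""

    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ParameterError("mask must be 2-D")

    @property
    def coverage_fraction(self) -> float:
        return float(self.mask.mean()) if self.mask.size else 0.0

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorized point-in-tissue test (points outside the raster are False)."""
        x = np.asarray(np.floor(x), dtype=int)
        y = np.asarray(np.floor(y), dtype=int)
        h, w = self.mask.shape
        ok = (x >= 0) & (x < w) & (y >= 0) & (y < h)
        out = np.zeros(np.shape(x), dtype=bool)
        out[ok] = self.mask[y[ok], x[ok]]
        return out

    @property
    def bounds(self) -> tuple[int, int, int, int]:
        """(x0, y0, x1, y1) bounding box of the True region (whole raster if empty)."""
        if not self.mask.any():
            return 0, 0, self.mask.shape[1], self.mask.shape[0]
        ys, xs = np.nonzero(self.mask)
        return int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1


@dataclass
class TileGrid:
    """Half-open pixel rectangles (x0, y0, x1, y1) covering an image."""

    tile_size: int
    overlap: int
    tiles: list[tuple[int, int, int, int]] = field(default_factory=list)

    @property
    def stride(self) -> int:
        return self.tile_size - self.overlap

    def __len__(self) -> int:
        return len(self.tiles)

    def __iter__(self):
        return iter(self.tiles)


# ---------------------------------------------------------------------------
# operations

def blur_inplace_chunked(channel: np.ndarray, sigma: float, block: int = 512) -> None:
    """Gaussian blur a 2-D channel in place, in fixed row blocks with a halo
    wide enough (4 sigma) that the result equals the full-frame filter.
    Bounds temporary memory on slide-sized rasters."""
    from scipy import ndimage as ndi

    h = channel.shape[0]
    halo = int(np.ceil(4 * sigma)) + 1
    if block <= halo:
        raise ParameterError("block must exceed the blur halo")
    saved = channel[0:0]  # original rows feeding the next block's top halo
    for y0 in range(0, h, block):
        y1 = min(y0 + block, h)
        a0, a1 = max(0, y0 - halo), min(h, y1 + halo)
        src = np.concatenate([saved, channel[y0:a1]], axis=0)
        blurred = ndi.gaussian_filter(src, sigma, mode="nearest")
        if y1 < h:  # keep the rows the next block's halo must see unblurred
            saved = channel[y1 - halo:y1].copy()
        channel[y0:y1] = blurred[y0 - a0:y0 - a0 + (y1 - y0)]


def load_image(path) -> RasterImage:
    """Load an 8-bit RGB TIFF/PNG/JPEG; grayscale inputs are promoted to RGB."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such image file: {path}")
    try:
        import imageio.v3 as iio

        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - any decode failure is a format error
        raise FormatError(f"could not read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim not in (2, 3):
        raise FormatError(f"unsupported image layout {arr.shape} in {path}")
    if arr.dtype == np.uint16:
        arr = (arr // 257).astype(np.uint8)
    return RasterImage(arr)


def save_image(image: RasterImage, path) -> None:
    import imageio.v3 as iio

    iio.imwrite(Path(path), image.pixels)


def preprocess(
    image: RasterImage,
    target_size: int = DEFAULT_TARGET_SIZE,
    white_balance: bool = False,
    contrast_stretch: bool = False,
) -> RasterImage:
    """Resize to ``target_size`` square by bicubic interpolation.

    Optional enhancement (gray-world white balance, 1-99 percentile contrast
    stretch) is off by default: scanners apply their own auto-correction and
    re-correcting would double it.  With enhancement off and the image
    already at target size, the operation is a pixel-identical no-op.
    """
    if target_size < 64:
        raise ParameterError(f"target_size must be >= 64, got {target_size}")
    px = image.pixels
    if px.shape[:2] != (target_size, target_size):
        from skimage.transform import resize

        shrinking = px.shape[0] > target_size or px.shape[1] > target_size
        out = resize(
            px.astype(np.float32) / 255.0,
            (target_size, target_size),
            order=3,
            mode="reflect",
            anti_aliasing=shrinking,
            preserve_range=True,
        )
        px = np.clip(np.round(out * 255.0), 0, 255).astype(np.uint8)
    if white_balance:
        px = _gray_world(px)
    if contrast_stretch:
        px = _stretch(px)
    mpp = image.microns_per_pixel
    if mpp is not None and image.width != target_size:
        mpp = mpp * image.width / target_size
    return RasterImage(px, mpp)


def _gray_world(px: np.ndarray) -> np.ndarray:
    f = px.astype(np.float64)
    means = f.reshape(-1, 3).mean(axis=0)
    gain = means.mean() / np.maximum(means, 1e-9)
    return np.clip(np.round(f * gain), 0, 255).astype(np.uint8)


def _stretch(px: np.ndarray, lo: float = 1.0, hi: float = 99.0) -> np.ndarray:
    f = px.astype(np.float64)
    a, b = np.percentile(f, [lo, hi])
    if b <= a:
        return px
    return np.clip(np.round((f - a) / (b - a) * 255.0), 0, 255).astype(np.uint8)


def compute_tissue_mask(
    image: RasterImage,
    luminance_threshold: float = 0.94,
    saturation_threshold: float = 0.06,
    min_object_px: int = 64,
) -> TissueMask:
    """Tissue = pixels that are not near-white background.

    A pixel counts as tissue if its luminance falls below
    ``luminance_threshold`` or its HSV-style saturation exceeds
    ``saturation_threshold``; speckles smaller than ``min_object_px`` are
    removed and holes inside tissue are filled.
    """
    # integer arithmetic throughout: big rasters, no float temporaries
    px = image.pixels
    r = px[..., 0].astype(np.uint32)
    g = px[..., 1].astype(np.uint32)
    b = px[..., 2].astype(np.uint32)
    lum256 = 77 * r + 150 * g + 29 * b  # 256 * luminance
    mx = np.maximum(np.maximum(r, g), b)
    mn = np.minimum(np.minimum(r, g), b)
    # sat = (mx - mn) / mx  >  s_thr   <=>   256*(mx - mn) > round(256*s_thr)*mx
    raw = (lum256 < luminance_threshold * 255.0 * 256.0) | (
        256 * (mx - mn) > int(round(saturation_threshold * 256)) * mx
    )
    if raw.any():
        from scipy import ndimage as ndi

        raw = ndi.binary_fill_holes(raw)
        lbl, n = ndi.label(raw)
        if n:
            sizes = np.bincount(lbl.ravel())
            keep = sizes >= min_object_px
            keep[0] = False
            raw = keep[lbl]
    return TissueMask(raw)


def tile_image(image, tile_size: int, overlap: int = 0) -> TileGrid:
    """Cover the image with half-open tiles of stride ``tile_size - overlap``.

    ``image`` may be a :class:`RasterImage` or an (height, width) pair.
    Border tiles are clipped and may be smaller.
    """
    if isinstance(image, RasterImage):
        h, w = image.shape
    else:
        h, w = int(image[0]), int(image[1])
    if overlap < 0:
        raise ParameterError("overlap must be >= 0")
    if tile_size <= overlap:
        raise ParameterError(f"tile_size ({tile_size}) must exceed overlap ({overlap})")
    stride = tile_size - overlap
    tiles = []
    for y0 in range(0, h, stride):
        y1 = min(y0 + tile_size, h)
        for x0 in range(0, w, stride):
            x1 = min(x0 + tile_size, w)
            tiles.append((x0, y0, x1, y1))
    return TileGrid(tile_size=tile_size, overlap=overlap, tiles=tiles)


def merge_tile_detections(
    per_tile_points: Sequence[Sequence[SignalPoint]] | Sequence[SignalPoint],
    min_separation: float,
) -> list[SignalPoint]:
    """Deduplicate detections reported by overlapping tiles.

    Greedy non-maximum suppression: points are visited by (strength desc,
    x asc, y asc); a point is kept iff no already-kept point lies strictly
    closer than ``min_separation``.  The result is independent of tile
    enumeration order.
    """
    flat: list[SignalPoint] = []
    for item in per_tile_points:
        if isinstance(item, SignalPoint):
            flat.append(item)
        else:
            flat.extend(item)
    if not flat:
        return []
    order = sorted(range(len(flat)), key=lambda i: (-flat[i].strength, flat[i].x, flat[i].y))
    xy = np.array([(flat[i].x, flat[i].y) for i in order])
    tree = cKDTree(xy)
    pairs = tree.query_pairs(min_separation, output_type="ndarray")
    if len(pairs):
        d = np.hypot(*(xy[pairs[:, 0]] - xy[pairs[:, 1]]).T)
        pairs = pairs[d < min_separation]
    conflicts: dict[int, list[int]] = {}
    for a, b in pairs:
        conflicts.setdefault(int(a), []).append(int(b))
        conflicts.setdefault(int(b), []).append(int(a))
    suppressed = np.zeros(len(order), dtype=bool)
    kept = []
    for rank in range(len(order)):
        if suppressed[rank]:
            continue
        kept.append(flat[order[rank]])
        for other in conflicts.get(rank, ()):
            if other > rank:
                suppressed[other] = True
    return kept
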