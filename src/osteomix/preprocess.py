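"""Preprocessing of two-channel stacks into binarized, tiled MIP data.

The order of operations mirrors the tiling-image workflow of intravital
skull imaging: maximum-intensity projection, gamma correction, a single
global Otsu threshold per channel over the stitched mosaic, a split into
equal tiles, and the red/cyan area-ratio tile filter (only tiles whose red
area is between 0.5× and 2× the cyan area are analyzed further).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import ConfigurationError, DataError, TwoChannelImage, TwoChannelVolume

__all__ = [
    "BinaryTile",
    "max_project",
    "gamma_correct",
    "otsu_threshold",
    "stitch_fields",
    "split_into_fields",
    "binarize_image",
    "stitch_and_tile",
    "ratio_filter",
    "RATIO_LO",
    "RATIO_HI",
]

#: red/cyan area-ratio bounds for a tile to be analyzed (closed interval)
RATIO_LO = 0.5
RATIO_HI = 2.0

_OTSU_BINS = 256


@dataclass
class BinaryTile:
    """One tile of the binarized mosaic, with per-channel areas and the
    ratio-filter verdict."""

    cyan_mask: np.ndarray
    red_mask: np.ndarray
    tile_index: tuple[int, int]
    pixel_size_um: float = 1.0
    pass_ratio_filter: bool = False

    @property
    def cyan_area_px(self) -> int:
        return int(self.cyan_mask.sum())

    @property
    def red_area_px(self) -> int:
        return int(self.red_mask.sum())

    @property
    def ratio(self) -> float:
        """red/cyan area ratio; NaN when the cyan area is zero."""
        if self.cyan_area_px == 0:
            return float("nan")
        return self.red_area_px / self.cyan_area_px


def max_project(volume: TwoChannelVolume) -> TwoChannelImage:
    """Per-pixel maximum over z, each channel independently."""
    if volume.shape[0] < 1:
        raise DataError("volume has no z-slices")
    return TwoChannelImage(
        cyan=volume.cyan.max(axis=0),
        red=volume.red.max(axis=0),
        pixel_size_um=volume.voxel_size_um[2],
    )


def gamma_correct(image: np.ndarray, gamma: float) -> np.ndarray:
    """Monotone gamma mapping within the image's own dynamic range.

    Intensities are rescaled to [0, 1] over the observed min–max, raised to
    ``gamma``, and rescaled back, so order is preserved and the range is
    unchanged. A constant image is returned unchanged.
    """
    if not gamma > 0:
        raise ConfigurationError("gamma must be > 0")
    image = np.asarray(image, dtype=np.float64)
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        return image.copy()
    norm = (image - lo) / (hi - lo)
    return norm**gamma * (hi - lo) + lo


def otsu_threshold(image: np.ndarray) -> tuple[float, np.ndarray]:
    """Otsu's automatic threshold over a 256-bin histogram.

    The histogram spans the observed min–max of the image regardless of bit
    depth. The returned threshold is the center of the highest bin assigned
    to background; the foreground mask is ``image > threshold``. Ties in
    between-class variance are broken toward the lower threshold.
    """
    image = np.asarray(image, dtype=np.float64)
    if np.unique(image).size < 2:
        raise DataError("degenerate histogram: image has fewer than 2 distinct values")
    counts, edges = np.histogram(image, bins=_OTSU_BINS)
    centers = (edges[:-1] + edges[1:]) / 2.0

    counts = counts.astype(np.float64)
    w0 = np.cumsum(counts)
    w1 = w0[-1] - w0
    cum = np.cumsum(counts * centers)
    # class means for every candidate split after bin t (t = 0..254)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = cum / w0
        mu1 = (cum[-1] - cum) / w1
        bcv = w0 * w1 * (mu0 - mu1) ** 2
    bcv = np.where((w0 > 0) & (w1 > 0), bcv, -np.inf)[:-1]
    t = int(np.argmax(bcv))  # argmax returns the first (lowest) maximizer
    threshold = float(centers[t])
    return threshold, image > threshold


def stitch_fields(fields: list[TwoChannelImage], grid: tuple[int, int]) -> TwoChannelImage:
    """Concatenate fields in row-major order into one mosaic."""
    rows, cols = grid
    if len(fields) != rows * cols:
        raise DataError(f"expected {rows * cols} fields for grid {grid}, got {len(fields)}")
    shapes = {f.shape for f in fields}
    if len(shapes) != 1:
        raise DataError(f"fields differ in shape: {sorted(shapes)}")
    px = {f.pixel_size_um for f in fields}
    if len(px) != 1:
        raise DataError("fields differ in pixel size")

    def block(channel: str) -> np.ndarray:
        return np.block(
            [
                [fields[i * cols + j].channel(channel) for j in range(cols)]
                for i in range(rows)
            ]
        )

    return TwoChannelImage(block("cyan"), block("red"), pixel_size_um=fields[0].pixel_size_um)


def split_into_fields(image: TwoChannelImage, grid: tuple[int, int]) -> list[TwoChannelImage]:
    """Inverse of :func:`stitch_fields`: cut a mosaic into equal fields."""
    rows, cols = grid
    h, w = image.shape
    if h % rows or w % cols:
        raise DataError(f"mosaic shape {image.shape} not divisible by grid {grid}")
    fh, fw = h // rows, w // cols
    return [
        TwoChannelImage(
            image.cyan[i * fh : (i + 1) * fh, j * fw : (j + 1) * fw],
            image.red[i * fh : (i + 1) * fh, j * fw : (j + 1) * fw],
            pixel_size_um=image.pixel_size_um,
        )
        for i in range(rows)
        for j in range(cols)
    ]


def ratio_filter(tile: BinaryTile, lo: float = RATIO_LO, hi: float = RATIO_HI) -> bool:
    """Tile passes iff red/cyan area ∈ [lo, hi] (closed) and cyan area > 0.

    A zero cyan area leaves the ratio undefined; such tiles fail rather than
    error — they are simply uninformative.
    """
    if tile.cyan_area_px == 0:
        return False
    r = tile.red_area_px / tile.cyan_area_px
    return lo <= r <= hi


def binarize_image(
    image: TwoChannelImage,
    tile_grid: tuple[int, int] = (4, 4),
    gamma: float = 1.0,
    ratio_lo: float = RATIO_LO,
    ratio_hi: float = RATIO_HI,
) -> list[BinaryTile]:
    """Gamma-correct and Otsu-binarize a mosaic (one global threshold per
    channel), then split into ``tile_grid`` equal tiles with the ratio filter
    applied per tile."""
    masks = {}
    for ch in ("cyan", "red"):
        corrected = gamma_correct(image.channel(ch), gamma)
        _, masks[ch] = otsu_threshold(corrected)
    rows, cols = tile_grid
    h, w = image.shape
    if h % rows or w % cols:
        raise DataError(f"image shape {image.shape} not divisible by tile grid {tile_grid}")
    th, tw = h // rows, w // cols
    tiles = []
    for i in range(rows):
        for j in range(cols):
            sl = np.s_[i * th : (i + 1) * th, j * tw : (j + 1) * tw]
            tile = BinaryTile(
                cyan_mask=masks["cyan"][sl],
                red_mask=masks["red"][sl],
                tile_index=(i, j),
                pixel_size_um=image.pixel_size_um,
            )
            tile.pass_ratio_filter = ratio_filter(tile, ratio_lo, ratio_hi)
            tiles.append(tile)
    return tiles


def stitch_and_tile(
    fields: list[TwoChannelImage],
    grid: tuple[int, int],
    tile_grid: tuple[int, int] = (4, 4),
    gamma: float = 1.0,
    ratio_lo: float = RATIO_LO,
    ratio_hi: float = RATIO_HI,
) -> list[BinaryTile]:
    """Stitch fields row-major, then binarize and tile the mosaic.

    Thresholding is global over the stitched image (per channel), not per
    tile, matching how tiling images are binarized before the per-field
    analysis.
    """
    mosaic = stitch_fields(fields, grid)
    return binarize_image(mosaic, tile_grid, gamma, ratio_lo, ratio_hi)
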