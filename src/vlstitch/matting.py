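"""Tissue/background separation ("matting") for fragment thumbnails.

Fragments are composited during stitching; an opaque rectangular scan
would occlude its neighbours, so each fragment gets a binary alpha mask:
255 on tissue, 0 on glass.  The mask is computed at thumbnail scale and
nearest-neighbour upsampled during full-resolution rendering.

The tissue signal is ``max(255 - brightness, saturation)``: eosin-pink
tissue has high saturation, hematoxylin-dark tissue has low brightness,
and bare glass has neither.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import closing, opening

from .fragment_io import RasterTile

__all__ = ["AlphaMask", "compute_alpha_mask", "apply_mask", "tissue_signal"]


@dataclass
class AlphaMask:
    """Binary per-pixel alpha aligned to a tile: values are only 0 or 255.

    ``factor`` records the downsample of the tile the mask was computed
    on relative to level 0 (64 for the stitching thumbnails); the
    renderer nearest-neighbour upsamples by this factor.
    """

    values: np.ndarray  # uint8, HxW
    factor: int = 1

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.uint8)
        if v.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not np.isin(v, (0, 255)).all():
            raise ValueError("mask values must be 0 or 255")
        self.values = v

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def foreground_count(self) -> int:
        return int((self.values == 255).sum())


def tissue_signal(rgb: np.ndarray) -> np.ndarray:
    """Per-pixel tissue evidence in [0, 255]: max of inverted brightness
    (value channel) and saturation, both scaled to 8 bits."""
    rgb = np.asarray(rgb, dtype=np.float64)
    mx = rgb.max(axis=-1)
    mn = rgb.min(axis=-1)
    sat = np.where(mx > 0, (mx - mn) / np.maximum(mx, 1e-12) * 255.0, 0.0)
    return np.maximum(255.0 - mx, sat)


def _drop_small_components(fg: np.ndarray, min_px: int) -> np.ndarray:
    labels, n = ndimage.label(fg)
    if n == 0:
        return fg
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_px
    keep[0] = False
    return keep[labels]


def compute_alpha_mask(
    tile: RasterTile,
    method: str = "otsu",
    fixed_threshold: int = 235,
    min_object_px: int = 64,
    factor: int = 1,
) -> AlphaMask:
    """Segment tissue foreground in an RGB tile.

    ``method='otsu'`` thresholds the tissue signal adaptively, capped at
    the conservative glass level ``255 - fixed_threshold`` so a strong
    dark-stain mode can never pull pale stroma into the background class;
    ``method='fixed'`` uses that cap directly (pixels darker than
    ``fixed_threshold`` brightness, or saturated, are tissue).  The raw
    mask is cleaned by 3x3 closing then opening, dropping components
    below ``min_object_px``, and filling enclosed holes.
    """
    if tile.width == 0 or tile.height == 0:
        raise ValueError("cannot mat an empty tile")
    if tile.channels != 3:
        raise ValueError("matting expects an RGB tile")
    sig = tissue_signal(tile.pixels)

    if method == "otsu":
        if np.ptp(sig) < 1e-9:
            # uniform tile: call it tissue only if clearly non-glass
            fg = np.full(sig.shape, sig.flat[0] > 20.0, dtype=bool)
        else:
            t = min(threshold_otsu(sig), 255.0 - fixed_threshold)
            fg = sig > t
    elif method == "fixed":
        if not 0 <= fixed_threshold <= 255:
            raise ValueError("fixed_threshold must be in [0, 255]")
        fg = sig > (255 - fixed_threshold)
    else:
        raise ValueError(f"unknown matting method {method!r}")

    se = np.ones((3, 3), dtype=bool)
    fg = closing(fg, se)
    fg = opening(fg, se)
    if min_object_px > 0:
        fg = _drop_small_components(fg, min_object_px)
    fg = ndimage.binary_fill_holes(fg)
    return AlphaMask(values=fg.astype(np.uint8) * 255, factor=factor)


def dilate_mask(mask: AlphaMask, px: int = 1) -> AlphaMask:
    """Grow the foreground by ``px`` mask pixels (8-connected).

    Rendering pipelines dilate the matting mask by one thumbnail pixel
    before compositing: a boundary block whose averaged signal fell just
    under threshold is then still painted, so no true tissue pixel is
    dropped at fragment edges.  The extra rim is glass and composites as
    background white.
    """
    if px < 0:
        raise ValueError("dilation radius must be >= 0")
    if px == 0:
        return AlphaMask(values=mask.values.copy(), factor=mask.factor)
    fg = ndimage.binary_dilation(mask.values == 255, iterations=px,
                                 structure=np.ones((3, 3), dtype=bool))
    return AlphaMask(values=fg.astype(np.uint8) * 255, factor=mask.factor)


def choose_mask_factor(width_l0: int, height_l0: int, preferred: int = 64,
                       min_dim: int = 64) -> int:
    """Largest power-of-two downsample <= ``preferred`` that keeps the
    masked thumbnail at least ``min_dim`` pixels on its short side.

    Gigapixel scans mat at the stitching-thumbnail scale (64x); small or
    already-downsampled fragments fall back to finer scales so the
    morphological cleanup still has pixels to work with.
    """
    f = preferred
    while f > 1 and min(width_l0, height_l0) // f < min_dim:
        f //= 2
    return max(f, 1)


def apply_mask(tile: RasterTile, mask: AlphaMask) -> RasterTile:
    """Attach a binary alpha channel to an RGB tile (RGB left untouched)."""
    if (tile.height, tile.width) != (mask.height, mask.width):
        raise ValueError(
            f"mask {mask.width}x{mask.height} does not match "
            f"tile {tile.width}x{tile.height}"
        )
    rgb = tile.pixels[..., :3]
    rgba = np.dstack([rgb, mask.values])
    return RasterTile(origin=tile.origin, pixels=rgba)
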