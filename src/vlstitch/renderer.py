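"""Lossless reconstruction of the virtual large slide.

Compositing follows a binary-alpha painter's rule: for every canvas
pixel the fragments are consulted in z-order and the top-most fragment
whose inverse-mapped source pixel is tissue (alpha 255) supplies the
RGB value unchanged; glass background stays opaque white.  No blending
ever happens, so each output pixel is a verbatim copy of exactly one
input pixel — for poses restricted to 90-degree steps, mirrors and
integer translations with nearest sampling the reconstruction is
pixel-exact.

Tile rendering is pure and deterministic, so a full render can run as a
background job, tile by tile in row-major order, without affecting
concurrent annotation work; progress is reported through a callback.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import ndimage

from .errors import LayoutError
from .fragment_io import (
    BACKGROUND_RGB,
    RasterTile,
    SlideFragment,
    write_pyramidal_tiff,
    default_n_levels,
)
from .layout import StitchLayout, canvas_bounds, pose_to_matrix, scale_pose, shift_layout
from .matting import AlphaMask

logger = logging.getLogger(__name__)

__all__ = ["RenderJob", "render_tile", "render_vls", "render_preview"]


@dataclass
class RenderJob:
    """A full-slide render: layout, resolved fragments, output settings.

    ``status`` only moves forward (pending -> running -> done/failed) and
    ``progress`` is monotonically non-decreasing in [0, 1].
    """

    layout: StitchLayout
    fragments: list[SlideFragment]
    out_path: str
    masks: Mapping[str, AlphaMask] | None = None
    interpolation: str = "nearest"
    tile_size: int = 256
    n_levels: int | None = None
    progress_callback: Callable[[float], None] | None = None
    status: str = "pending"
    progress: float = 0.0
    error: str | None = None

    def _advance(self, frac: float) -> None:
        self.progress = max(self.progress, min(frac, 1.0))
        if self.progress_callback is not None:
            self.progress_callback(self.progress)


def _resolve(fragments: Sequence[SlideFragment]) -> dict[str, SlideFragment]:
    return {f.fragment_id: f for f in fragments}


def _sample_fragment(
    frag: SlideFragment,
    inv: np.ndarray,
    xs: np.ndarray,
    ys: np.ndarray,
    mask: AlphaMask | None,
    interpolation: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse-map canvas pixel centers into a fragment and sample it.

    Returns (rgb, valid): ``valid`` is True where the source position lies
    inside the fragment and on tissue per the (thumbnail-scale, nearest-
    upsampled) alpha mask.
    """
    # xs, ys are already continuous canvas coordinates of pixel centers
    sx = inv[0, 0] * xs + inv[0, 1] * ys + inv[0, 2]
    sy = inv[1, 0] * xs + inv[1, 1] * ys + inv[1, 2]
    arr = frag.level_array(0)
    h, w = arr.shape[:2]
    ix = np.floor(sx).astype(np.int64)
    iy = np.floor(sy).astype(np.int64)
    valid = (ix >= 0) & (ix < w) & (iy >= 0) & (iy < h)
    ixc = np.clip(ix, 0, w - 1)
    iyc = np.clip(iy, 0, h - 1)

    if mask is not None:
        mx = np.clip(ixc // mask.factor, 0, mask.width - 1)
        my = np.clip(iyc // mask.factor, 0, mask.height - 1)
        valid &= mask.values[my, mx] == 255

    if interpolation == "nearest":
        rgb = arr[iyc, ixc]
    elif interpolation == "bilinear":
        coords = np.stack([sy - 0.5, sx - 0.5])
        rgb = np.stack(
            [
                ndimage.map_coordinates(
                    arr[..., c].astype(np.float64), coords, order=1, mode="nearest"
                )
                for c in range(3)
            ],
            axis=-1,
        )
        rgb = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
    else:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    return rgb, valid


def render_tile(
    layout: StitchLayout,
    fragments: Sequence[SlideFragment],
    level: int,
    tile_rect: tuple[int, int, int, int],
    masks: Mapping[str, AlphaMask] | None = None,
    interpolation: str = "nearest",
) -> RasterTile:
    """Render one canvas tile at pyramid level ``level``.

    ``tile_rect`` is (x, y, w, h) in level pixels.  ``masks`` maps
    fragment ids to thumbnail-scale alpha masks; a missing mask means the
    whole fragment is opaque tissue.
    """
    x0, y0, w, h = tile_rect
    if w < 1 or h < 1:
        raise ValueError("tile dimensions must be >= 1")
    by_id = _resolve(fragments)
    scale = 2.0**level

    ys, xs = np.mgrid[0:h, 0:w]
    # canvas level-0 continuous coordinates of the tile's pixel centers:
    # a level-L pixel covers a 2^L x 2^L level-0 square
    cx = (xs + x0 + 0.5) * scale
    cy = (ys + y0 + 0.5) * scale

    out = np.empty((h, w, 3), dtype=np.uint8)
    out[:] = BACKGROUND_RGB
    for pose in layout.sorted_poses():  # ascending z: later fragments on top
        frag = by_id.get(pose.fragment_id)
        if frag is None:
            raise LayoutError(f"unresolved fragment {pose.fragment_id!r}")
        p0 = scale_pose(pose, "level0")
        m = pose_to_matrix(p0, frag.width_l0, frag.height_l0)
        inv = np.linalg.inv(m)
        mask = None if masks is None else masks.get(pose.fragment_id)
        rgb, valid = _sample_fragment(frag, inv, cx, cy, mask, interpolation)
        out[valid] = rgb[valid]
    return RasterTile(origin=(x0, y0), pixels=out)


def render_vls(job: RenderJob) -> str:
    """Run a full reconstruction job and write the pyramidal TIFF.

    Tiles are rendered in deterministic row-major order, so re-running an
    identical job yields byte-identical level-0 pixel data.
    """
    job.status = "running"
    try:
        if not job.layout.poses:
            raise LayoutError("cannot render an empty layout")
        cw, ch, shift = canvas_bounds(job.layout, job.fragments)
        shifted = shift_layout(job.layout, shift)
        n_levels = job.n_levels or default_n_levels(cw, ch)
        total = (
            ((cw + job.tile_size - 1) // job.tile_size)
            * ((ch + job.tile_size - 1) // job.tile_size)
        )
        done = 0

        def provider(level: int, rect: tuple[int, int, int, int]) -> RasterTile:
            nonlocal done
            tile = render_tile(
                shifted, job.fragments, level, rect, job.masks, job.interpolation
            )
            done += 1
            job._advance(done / total)
            logger.info("rendered tile %d/%d at %s", done, total, rect[:2])
            return tile

        write_pyramidal_tiff(
            cw, ch, job.layout.mpp, provider, job.out_path,
            tile_size=job.tile_size, n_levels=n_levels,
        )
    except Exception as exc:
        job.status = "failed"
        job.error = str(exc)
        raise
    job.status = "done"
    job._advance(1.0)
    return job.out_path


def render_preview(
    layout: StitchLayout,
    thumbnails: Mapping[str, RasterTile],
    masks: Mapping[str, AlphaMask],
) -> RasterTile:
    """Composite thumbnail-scale fragments into the interactive preview.

    Same painter's rule as the full render, applied directly to the
    downsampled fragments; the result is RGBA with alpha 255 wherever any
    fragment covered the pixel.
    """
    f = layout.thumbnail_factor
    pts = []
    for pose in layout.poses:
        thumb = thumbnails.get(pose.fragment_id)
        mask = masks.get(pose.fragment_id)
        if thumb is None or mask is None:
            raise ValueError(f"missing thumbnail or mask for {pose.fragment_id!r}")
        if (thumb.height, thumb.width) != (mask.height, mask.width):
            raise ValueError(f"thumbnail/mask size mismatch for {pose.fragment_id!r}")
        pt = scale_pose(pose, "thumbnail")
        m = pose_to_matrix(pt, thumb.width, thumb.height)
        corners = np.array(
            [[0, 0, 1], [thumb.width, 0, 1], [0, thumb.height, 1],
             [thumb.width, thumb.height, 1]], dtype=float,
        )
        pts.append((m @ corners.T).T[:, :2])
    if not pts:
        raise LayoutError("layout has no poses")
    allpts = np.vstack(pts)
    mn = allpts.min(axis=0)
    mx = allpts.max(axis=0)
    w = max(int(np.ceil(mx[0] - mn[0])), 1)
    h = max(int(np.ceil(mx[1] - mn[1])), 1)

    out = np.empty((h, w, 4), dtype=np.uint8)
    out[..., :3] = BACKGROUND_RGB
    out[..., 3] = 0
    ys, xs = np.mgrid[0:h, 0:w]
    for pose in sorted(layout.poses, key=lambda p: p.z_order):
        thumb = thumbnails[pose.fragment_id]
        mask = masks[pose.fragment_id]
        pt = scale_pose(pose, "thumbnail")
        pt_shifted = pt
        pt_shifted.tx -= mn[0]
        pt_shifted.ty -= mn[1]
        m = pose_to_matrix(pt_shifted, thumb.width, thumb.height)
        inv = np.linalg.inv(m)
        sx = inv[0, 0] * (xs + 0.5) + inv[0, 1] * (ys + 0.5) + inv[0, 2]
        sy = inv[1, 0] * (xs + 0.5) + inv[1, 1] * (ys + 0.5) + inv[1, 2]
        ix = np.floor(sx).astype(np.int64)
        iy = np.floor(sy).astype(np.int64)
        valid = (ix >= 0) & (ix < thumb.width) & (iy >= 0) & (iy < thumb.height)
        ixc = np.clip(ix, 0, thumb.width - 1)
        iyc = np.clip(iy, 0, thumb.height - 1)
        valid &= mask.values[iyc, ixc] == 255
        rgb = thumb.pixels[iyc, ixc, :3]
        out[..., :3][valid] = rgb[valid]
        out[..., 3][valid] = 255
    return RasterTile(origin=(0, 0), pixels=out)
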