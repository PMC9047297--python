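"""Reading WSI fragments and writing reconstructed slides.

A *fragment* is one scanned piece of a sectioned tissue slab, stored as a
(possibly pyramidal) TIFF or a plain PNG.  Physical scale is carried as a
single isotropic microns-per-pixel (mpp) value, read from the TIFF
resolution tags or supplied through a ``<file>.mpp`` sidecar / explicit
override.  Reconstructed virtual large slides are written back out as
tiled, Deflate-compressed pyramidal TIFF so the output stays lossless and
openable by generic WSI readers.

Coordinates are 0-based, half-open, origin at the top-left, x to the
right and y down.  Region requests address level 0 unless stated.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import tifffile
from PIL import Image

from .errors import CalibrationError, FormatError

__all__ = [
    "SlideFragment",
    "RasterTile",
    "read_fragment",
    "read_region",
    "make_thumbnail",
    "write_pyramidal_tiff",
]

#: Opaque white: glass-slide background, used to pad out-of-bounds reads.
BACKGROUND_RGB = (255, 255, 255)

# Pillow refuses very large images by default; fragments are trusted input.
Image.MAX_IMAGE_PIXELS = None


@dataclass
class RasterTile:
    """A rectangular block of 8-bit RGB(A) pixels plus its origin.

    ``origin`` is the (x, y) of the tile's top-left corner in canvas or
    fragment pixels; ``pixels`` has shape (height, width, channels).
    """

    origin: tuple[int, int]
    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.uint8)
        if px.ndim != 3 or px.shape[2] not in (3, 4):
            raise ValueError("tile pixels must be HxWx3 (RGB) or HxWx4 (RGBA)")
        self.pixels = px

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def channels(self) -> int:
        return self.pixels.shape[2]


@dataclass
class SlideFragment:
    """One scanned tissue fragment with its pyramid and scale metadata.

    ``levels`` lists ``(downsample_factor, width, height)`` with level 0
    first (factor 1) and factors strictly increasing.  Pixel data is read
    lazily per level and cached.
    """

    fragment_id: str
    width_l0: int
    height_l0: int
    mpp: float
    levels: list[tuple[float, int, int]]
    source_path: str
    _arrays: dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.width_l0 < 1 or self.height_l0 < 1:
            raise ValueError("fragment dimensions must be >= 1 pixel")
        if not self.mpp > 0:
            raise CalibrationError(
                f"mpp must be positive for fragment {self.fragment_id!r}"
            )
        if not self.levels or self.levels[0][0] != 1:
            raise ValueError("level 0 must exist with downsample factor 1")
        factors = [f for f, _, _ in self.levels]
        if any(b <= a for a, b in zip(factors, factors[1:])):
            raise ValueError("downsample factors must strictly increase")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def level_array(self, level: int) -> np.ndarray:
        """Return the full RGB array of ``level`` (cached after first read)."""
        if level < 0 or level >= self.n_levels:
            raise IndexError(
                f"level {level} out of range for fragment {self.fragment_id!r} "
                f"with {self.n_levels} level(s)"
            )
        if level not in self._arrays:
            self._arrays[level] = _load_level(self.source_path, level)
        return self._arrays[level]


def _to_rgb(arr: np.ndarray) -> np.ndarray:
    """Coerce a decoded image array to HxWx3 uint8."""
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:  # drop alpha over white
        rgb = arr[..., :3].astype(np.float64)
        a = arr[..., 3:4].astype(np.float64) / 255.0
        arr = np.clip(rgb * a + 255.0 * (1.0 - a), 0, 255).astype(np.uint8)
    if arr.dtype != np.uint8:
        info = np.iinfo(arr.dtype) if np.issubdtype(arr.dtype, np.integer) else None
        if info is not None and info.max > 255:
            arr = (arr.astype(np.float64) / info.max * 255.0).round().astype(np.uint8)
        else:
            arr = arr.astype(np.uint8)
    return np.ascontiguousarray(arr[..., :3])


def _load_level(path: str, level: int) -> np.ndarray:
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            return _to_rgb(series.levels[level].asarray())
    if level != 0:
        raise IndexError("plain images have a single pyramid level")
    with Image.open(path) as im:
        return _to_rgb(np.array(im.convert("RGB")))


def _mpp_from_tiff_page(page: "tifffile.TiffPage") -> float | None:
    """Derive isotropic mpp from TIFF resolution tags, if present."""
    tags = page.tags
    if "XResolution" not in tags or "YResolution" not in tags:
        return None
    xr = tags["XResolution"].value
    yr = tags["YResolution"].value
    unit = tags["ResolutionUnit"].value if "ResolutionUnit" in tags else 2
    unit = int(unit)

    def ratio(v) -> float:
        if isinstance(v, tuple):
            num, den = v
            return num / den if den else 0.0
        return float(v)

    xres, yres = ratio(xr), ratio(yr)
    if xres <= 0 or yres <= 0:
        return None
    # microns per unit length
    per_unit = {2: 25400.0, 3: 10000.0}.get(unit)
    if per_unit is None:
        return None
    mpp_x = per_unit / xres
    mpp_y = per_unit / yres
    if abs(mpp_x - mpp_y) > 1e-6 * max(mpp_x, mpp_y):
        raise CalibrationError(
            f"anisotropic resolution (mpp_x={mpp_x:.6g}, mpp_y={mpp_y:.6g}); "
            "only isotropic fragments are supported"
        )
    return mpp_x


def _sidecar_mpp(path: str) -> float | None:
    sidecar = path + ".mpp"
    if os.path.exists(sidecar):
        with open(sidecar) as fh:
            try:
                return float(fh.read().strip())
            except ValueError as exc:
                raise CalibrationError(f"unparsable mpp sidecar {sidecar!r}") from exc
    return None


def read_fragment(
    path: str,
    mpp: float | None = None,
    fragment_id: str | None = None,
) -> SlideFragment:
    """Open a TIFF or PNG fragment and collect its pyramid + scale metadata.

    mpp resolution order: explicit ``mpp`` argument, then a ``<path>.mpp``
    sidecar file, then the TIFF resolution tags.  A fragment without any
    of these raises :class:`CalibrationError` naming the file.
    """
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path!r}")
    fragment_id = fragment_id or os.path.splitext(os.path.basename(path))[0]
    ext = os.path.splitext(path)[1].lower()

    levels: list[tuple[float, int, int]]
    tag_mpp: float | None = None
    try:
        if ext in (".tif", ".tiff"):
            with tifffile.TiffFile(path) as tf:
                series = tf.series[0]
                w0 = h0 = None
                levels = []
                for lv in series.levels:
                    shape = lv.shape
                    h, w = int(shape[0]), int(shape[1])
                    if w0 is None:
                        w0, h0 = w, h
                        factor = 1.0
                    else:
                        factor = round(w0 / w, 6)
                    levels.append((factor, w, h))
                tag_mpp = _mpp_from_tiff_page(tf.pages[0])
        else:
            with Image.open(path) as im:
                w0, h0 = im.size
            levels = [(1.0, int(w0), int(h0))]
    except CalibrationError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot read image {path!r}: {exc}") from exc

    resolved = mpp if mpp is not None else (_sidecar_mpp(path) or tag_mpp)
    if resolved is None:
        raise CalibrationError(
            f"no microns-per-pixel calibration for {path!r}: supply an mpp "
            "override or a sidecar file"
        )
    return SlideFragment(
        fragment_id=fragment_id,
        width_l0=int(w0),
        height_l0=int(h0),
        mpp=float(resolved),
        levels=levels,
        source_path=path,
    )


def fragment_from_array(
    arr: np.ndarray, mpp: float, fragment_id: str = "mem"
) -> SlideFragment:
    """Wrap an in-memory RGB array as a single-level fragment (no file)."""
    arr = _to_rgb(np.asarray(arr))
    h, w = arr.shape[:2]
    frag = SlideFragment(
        fragment_id=fragment_id,
        width_l0=w,
        height_l0=h,
        mpp=mpp,
        levels=[(1.0, w, h)],
        source_path="<memory>",
    )
    frag._arrays[0] = arr
    return frag


def read_region(
    frag: SlideFragment, level: int, x: int, y: int, w: int, h: int
) -> RasterTile:
    """Read a ``w x h`` (level pixels) region whose top-left corner is at
    level-0 coordinates ``(x, y)``.

    Regions extending past the fragment are padded with opaque white.
    """
    if level < 0 or level >= frag.n_levels:
        raise IndexError(f"level {level} does not exist ({frag.n_levels} levels)")
    if w < 1 or h < 1:
        raise ValueError("region width and height must be >= 1")
    factor = frag.levels[level][0]
    arr = frag.level_array(level)
    lh, lw = arr.shape[:2]
    # top-left corner in level pixels
    lx = int(math.floor(x / factor))
    ly = int(math.floor(y / factor))

    out = np.empty((h, w, 3), dtype=np.uint8)
    out[:] = BACKGROUND_RGB
    sx0, sx1 = max(lx, 0), min(lx + w, lw)
    sy0, sy1 = max(ly, 0), min(ly + h, lh)
    if sx0 < sx1 and sy0 < sy1:
        out[sy0 - ly : sy1 - ly, sx0 - lx : sx1 - lx] = arr[sy0:sy1, sx0:sx1]
    return RasterTile(origin=(x, y), pixels=out)


def make_thumbnail(frag: SlideFragment, factor: int = 64) -> RasterTile:
    """Downsample a fragment by ``factor`` (area resampling).

    The output is ``ceil(width_l0/factor) x ceil(height_l0/factor)``.  The
    closest pyramid level not finer than needed is used as the source so
    gigapixel fragments never decode level 0 just for a preview.
    """
    if factor < 1:
        raise ValueError("thumbnail factor must be >= 1")
    tw = math.ceil(frag.width_l0 / factor)
    th = math.ceil(frag.height_l0 / factor)
    # coarsest level whose downsample still <= factor
    best = 0
    for i, (f, _, _) in enumerate(frag.levels):
        if f <= factor:
            best = i
    arr = frag.level_array(best)
    if arr.shape[1] == tw and arr.shape[0] == th:
        return RasterTile(origin=(0, 0), pixels=arr.copy())
    im = Image.fromarray(arr).resize((tw, th), resample=Image.Resampling.BOX)
    return RasterTile(origin=(0, 0), pixels=np.array(im))


def _area_downsample_2x(arr: np.ndarray) -> np.ndarray:
    """Half an RGB array by 2x2 block averaging (odd edges padded by edge)."""
    h, w = arr.shape[:2]
    ph, pw = h + (h % 2), w + (w % 2)
    if ph != h or pw != w:
        arr = np.pad(arr, ((0, ph - h), (0, pw - w), (0, 0)), mode="edge")
    a = arr.astype(np.uint32)
    blocks = a[0::2, 0::2] + a[0::2, 1::2] + a[1::2, 0::2] + a[1::2, 1::2]
    return ((blocks + 2) // 4).astype(np.uint8)


def default_n_levels(canvas_w: int, canvas_h: int, floor_px: int = 1024) -> int:
    """Pyramid depth used when the caller does not specify one: halve until
    the larger canvas dimension is <= ``floor_px``."""
    n = 1
    m = max(canvas_w, canvas_h)
    while m > floor_px:
        m = math.ceil(m / 2)
        n += 1
    return n


def write_pyramidal_tiff(
    canvas_w: int,
    canvas_h: int,
    mpp: float,
    tile_provider: Callable[[int, tuple[int, int, int, int]], RasterTile],
    out_path: str,
    tile_size: int = 256,
    n_levels: int | None = None,
) -> str:
    """Write a tiled, Deflate-compressed pyramidal TIFF.

    ``tile_provider(level, (x, y, w, h))`` supplies level-0 tiles in a
    deterministic row-major order; coarser levels are 2x area downsamples
    computed here, so level k is exactly the level-0 plane reduced by 2^k.
    mpp is recorded in the resolution tags (pixels per centimeter).
    Level-0 pixels round-trip bit-identically.
    """
    if canvas_w < 1 or canvas_h < 1:
        raise ValueError("canvas dimensions must be >= 1")
    if tile_size < 1 or (tile_size & (tile_size - 1)) != 0:
        raise ValueError("tile_size must be a power of two")
    if n_levels is None:
        n_levels = default_n_levels(canvas_w, canvas_h)

    level0 = np.empty((canvas_h, canvas_w, 3), dtype=np.uint8)
    for ty in range(0, canvas_h, tile_size):
        for tx in range(0, canvas_w, tile_size):
            w = min(tile_size, canvas_w - tx)
            h = min(tile_size, canvas_h - ty)
            tile = tile_provider(0, (tx, ty, w, h))
            if tile.pixels.shape[:2] != (h, w):
                raise ValueError(
                    f"tile provider returned {tile.pixels.shape[:2]} for a "
                    f"{h}x{w} request at ({tx},{ty})"
                )
            level0[ty : ty + h, tx : tx + w] = tile.pixels[..., :3]

    planes = [level0]
    for _ in range(n_levels - 1):
        planes.append(_area_downsample_2x(planes[-1]))

    ppcm = 1e4 / mpp
    opts = dict(
        tile=(tile_size, tile_size),
        compression="zlib",
        photometric="rgb",
        resolutionunit="CENTIMETER",
    )
    try:
        with tifffile.TiffWriter(out_path) as tw:
            tw.write(planes[0], subifds=len(planes) - 1,
                     resolution=(ppcm, ppcm), **opts)
            for k, plane in enumerate(planes[1:], start=1):
                tw.write(plane, subfiletype=1,
                         resolution=(ppcm / 2**k, ppcm / 2**k), **opts)
    except OSError as exc:
        raise IOError(f"failed writing {out_path!r}: {exc}") from exc
    return out_path
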