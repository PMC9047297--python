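"""Fragment poses and the stitch layout.

Each fragment carries a rigid pose on the shared canvas: an optional
horizontal/vertical mirror, a rotation about the fragment's geometric
center, and a translation.  Poses are edited interactively at thumbnail
scale (fragments downsampled 64-fold by default) and scaled to level-0
pixels for the lossless reconstruction; only the translation changes
between the two spaces.

Geometry conventions
--------------------
Coordinates are continuous with the pixel ``(i, j)`` covering the unit
square ``[i, i+1) x [j, j+1)`` and sampled at its center
``(i + 0.5, j + 0.5)``; x grows right, y grows down.  ``rotation_deg`` is
positive counter-clockwise as seen on screen, so at 90 degrees the
top-left corner of a square fragment moves to the bottom-left.  Mirrors
are applied before the rotation; with this convention every pose matrix
is ``T(tx, ty) . T(c) . R(theta) . F . T(-c)`` with ``c = (w/2, h/2)``.
Rotations by multiples of 90 degrees map the pixel grid onto itself
exactly, which is the lossless fast path.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import LayoutError
from .fragment_io import SlideFragment

__all__ = [
    "FragmentPose",
    "StitchLayout",
    "pose_to_matrix",
    "scale_pose",
    "canvas_bounds",
    "save_layout",
    "load_layout",
]

LAYOUT_SCHEMA_VERSION = 1


@dataclass
class FragmentPose:
    """Rigid placement of one fragment on the canvas.

    ``tx, ty`` translate the fragment after mirroring and rotating about
    its center; ``scale_space`` records whether they are thumbnail or
    level-0 pixels.  ``z_order`` resolves overlaps: higher is on top.
    """

    fragment_id: str
    rotation_deg: float = 0.0
    flip_h: bool = False
    flip_v: bool = False
    tx: float = 0.0
    ty: float = 0.0
    z_order: int = 0
    scale_space: str = "level0"
    thumbnail_factor: int = 64
    path: str | None = None

    def __post_init__(self) -> None:
        self.rotation_deg = float(self.rotation_deg) % 360.0
        if self.scale_space not in ("thumbnail", "level0"):
            raise ValueError(f"unknown scale_space {self.scale_space!r}")
        if self.thumbnail_factor < 1:
            raise ValueError("thumbnail_factor must be >= 1")


@dataclass
class StitchLayout:
    """The full stitch record: poses plus shared canvas metadata."""

    poses: list[FragmentPose]
    mpp: float
    thumbnail_factor: int = 64
    reference_image: str | None = None

    def __post_init__(self) -> None:
        zs = [p.z_order for p in self.poses]
        if len(set(zs)) != len(zs):
            raise LayoutError("z_order values must be unique within a layout")
        if not self.mpp > 0:
            raise LayoutError("layout mpp must be positive")

    def sorted_poses(self) -> list[FragmentPose]:
        return sorted(self.poses, key=lambda p: p.z_order)


def _linear_part(rotation_deg: float, flip_h: bool, flip_v: bool) -> np.ndarray:
    if rotation_deg % 90.0 == 0.0:
        # exact fast path: 90-degree steps map the pixel grid onto itself
        k = int(rotation_deg // 90) % 4
        c, s = [(1, 0), (0, 1), (-1, 0), (0, -1)][k]
    else:
        th = math.radians(rotation_deg)
        c, s = math.cos(th), math.sin(th)
    # screen-CCW rotation in y-down coordinates
    rot = np.array([[c, s], [-s, c]], dtype=float)
    flip = np.diag([-1.0 if flip_h else 1.0, -1.0 if flip_v else 1.0])
    return rot @ flip


def pose_to_matrix(pose: FragmentPose, frag_w: int, frag_h: int) -> np.ndarray:
    """3x3 homogeneous matrix mapping fragment pixels to canvas pixels.

    Mirrors first, then rotation about the fragment center ``(w/2, h/2)``,
    then translation by ``(tx, ty)``.  The linear part has determinant
    +/-1, so stitched measurements keep their physical scale.
    """
    if frag_w < 1 or frag_h < 1:
        raise ValueError("fragment dimensions must be >= 1")
    lin = _linear_part(pose.rotation_deg, pose.flip_h, pose.flip_v)
    c = np.array([frag_w / 2.0, frag_h / 2.0])
    m = np.eye(3)
    m[:2, :2] = lin
    m[:2, 2] = c - lin @ c + np.array([pose.tx, pose.ty])
    return m


def scale_pose(pose: FragmentPose, to_space: str) -> FragmentPose:
    """Rescale a pose's translation between thumbnail and level-0 space.

    Rotation and mirrors are scale-free; only ``tx, ty`` are multiplied
    (or divided) by the thumbnail factor, so the round trip is exact.
    """
    if to_space not in ("thumbnail", "level0"):
        raise ValueError(f"unknown scale space {to_space!r}")
    if pose.scale_space == to_space:
        return replace(pose)
    f = float(pose.thumbnail_factor)
    if to_space == "level0":
        return replace(pose, tx=pose.tx * f, ty=pose.ty * f, scale_space="level0")
    return replace(pose, tx=pose.tx / f, ty=pose.ty / f, scale_space="thumbnail")


def transformed_corners(
    pose: FragmentPose, frag_w: int, frag_h: int
) -> np.ndarray:
    """Canvas positions of the fragment's four geometric corners (4x2)."""
    m = pose_to_matrix(pose, frag_w, frag_h)
    corners = np.array(
        [[0, 0, 1], [frag_w, 0, 1], [0, frag_h, 1], [frag_w, frag_h, 1]], dtype=float
    )
    return (m @ corners.T).T[:, :2]


def canvas_bounds(
    layout: StitchLayout, fragments: Sequence[SlideFragment]
) -> tuple[int, int, tuple[float, float]]:
    """Canvas size covering every transformed fragment, and the shift that
    moves the joint bounding box's min corner to the origin.

    The shift must be applied uniformly (add it to every pose's
    translation) before rendering so no fragment lands at negative
    coordinates.
    """
    by_id = {f.fragment_id: f for f in fragments}
    pts = []
    for pose in layout.poses:
        frag = by_id.get(pose.fragment_id)
        if frag is None:
            raise LayoutError(f"pose references unknown fragment {pose.fragment_id!r}")
        p0 = scale_pose(pose, "level0")
        pts.append(transformed_corners(p0, frag.width_l0, frag.height_l0))
    if not pts:
        raise LayoutError("layout has no poses")
    allpts = np.vstack(pts)
    mn = allpts.min(axis=0)
    mx = allpts.max(axis=0)
    shift = (-mn[0], -mn[1])
    # round away accumulated float noise before snapping to whole pixels
    w = int(math.ceil(round(mx[0] - mn[0], 6)))
    h = int(math.ceil(round(mx[1] - mn[1], 6)))
    return max(w, 1), max(h, 1), shift


def shift_layout(layout: StitchLayout, shift: tuple[float, float]) -> StitchLayout:
    """Return a copy with every level-0 translation offset by ``shift``."""
    poses = []
    for pose in layout.poses:
        p0 = scale_pose(pose, "level0")
        poses.append(replace(p0, tx=p0.tx + shift[0], ty=p0.ty + shift[1]))
    return StitchLayout(
        poses=poses,
        mpp=layout.mpp,
        thumbnail_factor=layout.thumbnail_factor,
        reference_image=layout.reference_image,
    )


def save_layout(layout: StitchLayout, path: str) -> str:
    """Serialize a layout to versioned JSON (floats at full precision)."""
    doc = {
        "version": LAYOUT_SCHEMA_VERSION,
        "mpp": layout.mpp,
        "thumbnail_factor": layout.thumbnail_factor,
        "reference_image": layout.reference_image,
        "poses": [
            {
                "fragment_id": p.fragment_id,
                "path": p.path,
                "rotation_deg": p.rotation_deg,
                "flip_h": p.flip_h,
                "flip_v": p.flip_v,
                "tx": p.tx,
                "ty": p.ty,
                "z_order": p.z_order,
                "scale_space": p.scale_space,
                "thumbnail_factor": p.thumbnail_factor,
            }
            for p in layout.poses
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
    return path


def load_layout(path: str) -> StitchLayout:
    """Parse a layout JSON file; ``save_layout`` then ``load_layout`` is
    the identity on every pose field."""
    if not os.path.exists(path):
        raise LayoutError(f"no such layout file: {path!r}")
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise LayoutError(f"malformed layout JSON in {path!r}: {exc}") from exc
    if not isinstance(doc, dict) or "poses" not in doc:
        raise LayoutError(f"layout file {path!r} missing 'poses'")
    version = doc.get("version")
    if version != LAYOUT_SCHEMA_VERSION:
        raise LayoutError(f"unsupported layout schema version {version!r}")
    poses = []
    for rec in doc["poses"]:
        try:
            poses.append(
                FragmentPose(
                    fragment_id=rec["fragment_id"],
                    rotation_deg=rec.get("rotation_deg", 0.0),
                    flip_h=bool(rec.get("flip_h", False)),
                    flip_v=bool(rec.get("flip_v", False)),
                    tx=float(rec.get("tx", 0.0)),
                    ty=float(rec.get("ty", 0.0)),
                    z_order=int(rec["z_order"]),
                    scale_space=rec.get("scale_space", "level0"),
                    thumbnail_factor=int(
                        rec.get("thumbnail_factor", doc.get("thumbnail_factor", 64))
                    ),
                    path=rec.get("path"),
                )
            )
        except KeyError as exc:
            raise LayoutError(f"pose record missing field {exc}") from exc
    return StitchLayout(
        poses=poses,
        mpp=float(doc["mpp"]),
        thumbnail_factor=int(doc.get("thumbnail_factor", 64)),
        reference_image=doc.get("reference_image"),
    )
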