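"""Synthetic sectioned-slab fixtures with closed-form ground truth.

A synthetic "largest tumor-bed cross-section" is drawn from ellipses on
a white canvas: a pale-pink tumor bed, darker invasive-carcinoma blobs
and violet in-situ blobs, all strictly inside the bed and pairwise
disjoint.  Ellipse geometry gives every ground-truth quantity a closed
form — the bed diameters are twice the semi-axes and every area is
``pi * a * b`` — so measurement recovery can be checked without a
reference segmentation.

The section is then "grossed": cut into 2-8 near-vertical strips
(mimicking serial sectioning of the slab), each strip independently
mirrored, rotated and saved as its own calibrated fragment, exactly as
scanned slides arrive with arbitrary orientation.  The returned layout
holds the inverse of each perturbation, so rendering it reconstructs
the section; an optional per-cut gap emulates tissue lost to the blade.

A companion rater simulator produces subjects x raters tables
(continuous truth + Gaussian noise, categorical truth with symmetric
confusion) for the reliability statistics.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image as PILImage
from shapely.geometry import Polygon

from .fragment_io import SlideFragment, fragment_from_array, write_pyramidal_tiff, RasterTile
from .layout import FragmentPose, StitchLayout, transformed_corners
from .measure import AnnotationSet, TumorBedMetrics
from .reliability import RatingTable

__all__ = [
    "Ellipse",
    "SectionSpec",
    "CutPlan",
    "RaterSim",
    "default_section_spec",
    "generate_section",
    "fragment_section",
    "simulate_raters",
]

#: Flat stain palette: glass, bed stroma, invasive carcinoma, CIS.
DEFAULT_PALETTE = {
    "background": (255, 255, 255),
    "tumor_bed": (242, 199, 208),
    "invasive": (188, 96, 122),
    "cis": (120, 64, 130),
}

ELLIPSE_VERTICES = 256  # divisible by 4: polygon hits both axis extremes


@dataclass(frozen=True)
class Ellipse:
    """An ellipse in section millimetres: center, semi-axes, CCW angle."""

    cx_mm: float
    cy_mm: float
    a_mm: float  # semi-axis along the (rotated) x direction
    b_mm: float
    angle_deg: float = 0.0

    @property
    def area_mm2(self) -> float:
        return math.pi * self.a_mm * self.b_mm

    def polygon_px(self, mpp: float, n: int = ELLIPSE_VERTICES) -> Polygon:
        """Inscribed n-gon in canvas pixels (n divisible by 4 keeps the
        axis endpoints, so polygon diameters equal the true diameters)."""
        t = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
        x = self.a_mm * np.cos(t)
        y = self.b_mm * np.sin(t)
        th = math.radians(self.angle_deg)
        xr = self.cx_mm + x * math.cos(th) - y * math.sin(th)
        yr = self.cy_mm + x * math.sin(th) + y * math.cos(th)
        scale = 1000.0 / mpp  # mm -> px
        return Polygon(np.column_stack([xr * scale, yr * scale]))

    def contains_grid(self, xs_mm: np.ndarray, ys_mm: np.ndarray) -> np.ndarray:
        th = math.radians(self.angle_deg)
        dx = xs_mm - self.cx_mm
        dy = ys_mm - self.cy_mm
        u = dx * math.cos(th) + dy * math.sin(th)
        v = -dx * math.sin(th) + dy * math.cos(th)
        return (u / self.a_mm) ** 2 + (v / self.b_mm) ** 2 <= 1.0


@dataclass
class SectionSpec:
    """Geometry and staining of one synthetic cross-section.

    Nodal data rides along so the fixture defines a complete residual-
    cancer-burden case, not just an image.
    """

    canvas_mm: tuple[float, float] = (40.0, 30.0)
    mpp: float = 32.0
    bed: Ellipse = field(default_factory=lambda: Ellipse(20.0, 15.0, 15.0, 10.0))
    invasive_blobs: tuple[Ellipse, ...] = (Ellipse(17.0, 15.0, 9.0, 4.5),)
    cis_blobs: tuple[Ellipse, ...] = (Ellipse(28.0, 11.0, 3.0, 1.5),)
    palette: dict = field(default_factory=lambda: dict(DEFAULT_PALETTE))
    noise: float = 5.0  # uniform +/- noise on tissue pixels, 8-bit units
    n_pos_nodes: int = 2
    d_met_mm: float = 5.0
    seed: int = 0

    def truth_metrics(self) -> TumorBedMetrics:
        """Closed-form ground truth from the ellipse parameters."""
        a_bed = self.bed.area_mm2
        a_inv = sum(e.area_mm2 for e in self.invasive_blobs)
        a_cis = sum(e.area_mm2 for e in self.cis_blobs)
        a_ca = a_inv + a_cis
        return TumorBedMetrics(
            length_mm=2.0 * max(self.bed.a_mm, self.bed.b_mm),
            width_mm=2.0 * min(self.bed.a_mm, self.bed.b_mm),
            pct_ca=100.0 * a_ca / a_bed,
            pct_cis=100.0 * a_cis / a_ca if a_ca > 0 else 0.0,
        )


def default_section_spec(seed: int = 0) -> SectionSpec:
    """The stock fixture: a 30 x 20 mm bed holding 27% invasive carcinoma
    and 3% CIS by area (so pct_ca = 30, pct_cis = 10), with two positive
    nodes carrying a 5 mm largest metastasis."""
    return SectionSpec(seed=seed)


def generate_section(
    spec: SectionSpec,
) -> tuple[np.ndarray, AnnotationSet, TumorBedMetrics]:
    """Rasterize a section and emit matching annotations and ground truth.

    Returns ``(image, annotations, truth)``: an RGB uint8 array, the
    ellipses as labeled polygons in canvas pixels, and the analytic
    metrics.  Identical specs (including seed) produce identical bytes.
    """
    bed_poly = spec.bed.polygon_px(spec.mpp)
    blobs = [(e, "invasive") for e in spec.invasive_blobs] + [
        (e, "cis") for e in spec.cis_blobs
    ]
    polys = []
    for e, label in blobs:
        p = e.polygon_px(spec.mpp)
        if not p.within(bed_poly):
            raise ValueError(f"{label} blob {e} is not strictly inside the bed")
        polys.append((p, label))
    for i in range(len(polys)):
        for j in range(i + 1, len(polys)):
            if polys[i][0].intersects(polys[j][0]):
                raise ValueError(
                    "carcinoma blobs must be pairwise disjoint for the "
                    "analytic truth to hold"
                )

    w_px = int(round(spec.canvas_mm[0] * 1000.0 / spec.mpp))
    h_px = int(round(spec.canvas_mm[1] * 1000.0 / spec.mpp))
    # pixel centers in mm
    xs = (np.arange(w_px) + 0.5) * spec.mpp / 1000.0
    ys = (np.arange(h_px) + 0.5) * spec.mpp / 1000.0
    gx, gy = np.meshgrid(xs, ys)

    img = np.empty((h_px, w_px, 3), dtype=np.uint8)
    img[:] = spec.palette["background"]
    in_bed = spec.bed.contains_grid(gx, gy)
    img[in_bed] = spec.palette["tumor_bed"]
    for e in spec.invasive_blobs:
        img[e.contains_grid(gx, gy)] = spec.palette["invasive"]
    for e in spec.cis_blobs:
        img[e.contains_grid(gx, gy)] = spec.palette["cis"]

    if spec.noise > 0:
        rng = np.random.default_rng(spec.seed)
        jitter = rng.integers(
            -int(spec.noise), int(spec.noise) + 1, size=img.shape, dtype=np.int16
        )
        tissue = in_bed[..., None]
        noisy = img.astype(np.int16) + np.where(tissue, jitter, 0)
        img = np.clip(noisy, 0, 254).astype(np.uint8)  # keep tissue off pure white

    features = [(bed_poly, "tumor_bed")] + polys
    annotations = AnnotationSet(features=features, mpp=spec.mpp)
    return img, annotations, spec.truth_metrics()


@dataclass
class CutPlan:
    """How to gross the section into fragments.

    Cuts are near-vertical with positional jitter; ``gap_px`` columns are
    lost at each cut (blade kerf).  Each fragment is independently
    mirrored with probability ``flip_prob`` and rotated by a choice from
    ``angle_choices_deg`` (90-degree steps by default, the lossless
    path; set ``free_angle_max_deg`` for arbitrary small angles instead).
    """

    n_fragments: int = 4
    gap_px: int = 0
    jitter_px: int = 8
    flip_prob: float = 0.5
    angle_choices_deg: tuple[float, ...] = (0.0, 90.0, 180.0, 270.0)
    free_angle_max_deg: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.n_fragments <= 8:
            raise ValueError("n_fragments must be between 2 and 8")
        if self.gap_px < 0 or self.jitter_px < 0:
            raise ValueError("gap_px and jitter_px must be >= 0")


def _inverse_rigid_90(arr: np.ndarray, rot_deg: float, fh: bool, fv: bool) -> np.ndarray:
    """Apply the inverse of (rotate rot_deg . mirror) to an array, for
    rotations that are multiples of 90 degrees."""
    k = int(round(rot_deg / 90.0)) % 4
    out = np.rot90(arr, -k)  # rotate by -rot_deg (np.rot90 is screen-CCW)
    if fh:
        out = out[:, ::-1]
    if fv:
        out = out[::-1, :]
    return np.ascontiguousarray(out)


def _place_pose(
    fragment_id: str,
    scanned_w: int,
    scanned_h: int,
    rot_deg: float,
    fh: bool,
    fv: bool,
    target_xy: tuple[float, float],
    z: int,
) -> FragmentPose:
    """Build the pose that maps a scanned fragment back onto the canvas so
    its transformed bounding box lands at ``target_xy``."""
    pose = FragmentPose(
        fragment_id=fragment_id, rotation_deg=rot_deg, flip_h=fh, flip_v=fv,
        tx=0.0, ty=0.0, z_order=z,
    )
    corners = transformed_corners(pose, scanned_w, scanned_h)
    mn = corners.min(axis=0)
    return replace(pose, tx=target_xy[0] - mn[0], ty=target_xy[1] - mn[1])


def _write_fragment_tiff(arr: np.ndarray, mpp: float, path: str) -> None:
    write_pyramidal_tiff(
        arr.shape[1], arr.shape[0], mpp,
        lambda level, rect: RasterTile(
            origin=rect[:2],
            pixels=arr[rect[1] : rect[1] + rect[3], rect[0] : rect[0] + rect[2]],
        ),
        path, tile_size=256, n_levels=2 if max(arr.shape[:2]) > 512 else 1,
    )


def fragment_section(
    image: np.ndarray,
    annotations: AnnotationSet,
    plan: CutPlan,
    out_dir: str | None = None,
) -> tuple[list[SlideFragment], StitchLayout]:
    """Cut a section into perturbed fragments plus the true stitch layout.

    Rendering the returned layout reconstructs the section (exactly, for
    the default 90-degree perturbations and zero gap).  When ``out_dir``
    is given the fragments are written as calibrated TIFFs and a
    degraded grayscale "x-ray guide" PNG is emitted alongside; otherwise
    the fragments stay in memory.
    """
    h, w = image.shape[:2]
    rng = np.random.default_rng(plan.seed)
    n = plan.n_fragments
    base = np.linspace(0, w, n + 1)
    cuts = [0]
    for i in range(1, n):
        j = rng.integers(-plan.jitter_px, plan.jitter_px + 1) if plan.jitter_px else 0
        cuts.append(int(np.clip(base[i] + j, cuts[-1] + 1, w - (n - i))))
    cuts.append(w)

    fragments: list[SlideFragment] = []
    poses: list[FragmentPose] = []
    xray_path = None
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        xray_path = os.path.join(out_dir, "xray_guide.png")
        _write_xray_guide(image, xray_path)

    for i in range(n):
        a, b = cuts[i], cuts[i + 1]
        if i < n - 1:
            b = max(b - plan.gap_px, a + 1)
        crop = image[:, a:b]
        if plan.free_angle_max_deg is not None:
            rot = float(rng.uniform(-plan.free_angle_max_deg, plan.free_angle_max_deg)) % 360.0
        else:
            rot = float(rng.choice(plan.angle_choices_deg))
        fh = bool(rng.random() < plan.flip_prob)
        fv = bool(rng.random() < plan.flip_prob)
        if plan.free_angle_max_deg is not None:
            # free angles cannot be realized exactly on the pixel grid;
            # the scanned fragment keeps the crop's orientation and the
            # pose records only mirrors
            scanned = _inverse_rigid_90(crop, 0.0, fh, fv)
            rot = 0.0
        else:
            scanned = _inverse_rigid_90(crop, rot, fh, fv)
        frag_id = f"frag_{i:02d}"
        if out_dir is not None:
            path = os.path.join(out_dir, f"{frag_id}.tiff")
            _write_fragment_tiff(scanned, annotations.mpp, path)
            frag = fragment_from_array(scanned, annotations.mpp, frag_id)
            frag.source_path = path
        else:
            path = None
            frag = fragment_from_array(scanned, annotations.mpp, frag_id)
        fragments.append(frag)
        pose = _place_pose(
            frag_id, scanned.shape[1], scanned.shape[0], rot, fh, fv,
            (float(a), 0.0), z=i,
        )
        pose.path = path
        poses.append(pose)

    layout = StitchLayout(
        poses=poses, mpp=annotations.mpp, thumbnail_factor=64,
        reference_image=xray_path,
    )
    return fragments, layout


def _write_xray_guide(image: np.ndarray, path: str, factor: int = 8) -> None:
    """A deliberately degraded grayscale preview standing in for the
    pre-scanned radiograph used as a stitching aid."""
    im = PILImage.fromarray(image).convert("L")
    small = im.resize(
        (max(im.width // factor, 1), max(im.height // factor, 1)),
        resample=PILImage.Resampling.BOX,
    )
    small.save(path)


@dataclass
class RaterSim:
    """Generative model for a simulated reader panel.

    Continuous variables: each rater reports truth + independent Gaussian
    noise (sd per variable), clipped to the variable's valid range.
    Categorical variables: symmetric confusion — with probability
    ``confusion_prob`` a rating is redrawn uniformly over the full
    category set (so confusion 1 means category-blind raters and
    chance-level agreement, not a systematic relabel).
    """

    continuous_truth: dict[str, np.ndarray] = field(default_factory=dict)
    continuous_sd: dict[str, float] = field(default_factory=dict)
    continuous_range: dict[str, tuple[float, float]] = field(default_factory=dict)
    categorical_truth: dict[str, np.ndarray] = field(default_factory=dict)
    categories: dict[str, tuple] = field(default_factory=dict)
    confusion_prob: float = 0.1
    n_raters: int = 5
    seed: int = 0


def simulate_raters(sim: RaterSim) -> dict[str, RatingTable]:
    """Draw one complete subjects x raters table per simulated variable."""
    if sim.n_raters < 2:
        raise ValueError("need at least 2 raters")
    rng = np.random.default_rng(sim.seed)
    tables: dict[str, RatingTable] = {}
    for name, truth in sim.continuous_truth.items():
        truth = np.asarray(truth, dtype=float)
        sd = sim.continuous_sd.get(name, 0.0)
        vals = truth[:, None] + rng.normal(0.0, sd, size=(len(truth), sim.n_raters)) if sd > 0 else np.tile(truth[:, None], (1, sim.n_raters))
        lo, hi = sim.continuous_range.get(name, (-np.inf, np.inf))
        tables[name] = RatingTable(np.clip(vals, lo, hi), kind="continuous")
    for name, truth in sim.categorical_truth.items():
        truth = np.asarray(truth, dtype=object)
        cats = tuple(sim.categories.get(name) or sorted(set(truth.tolist())))
        n = len(truth)
        vals = np.tile(truth[:, None], (1, sim.n_raters))
        if sim.confusion_prob > 0 and len(cats) > 1:
            flip = rng.random((n, sim.n_raters)) < sim.confusion_prob
            draws = rng.integers(len(cats), size=(n, sim.n_raters))
            for i in range(n):
                for j in range(sim.n_raters):
                    if flip[i, j]:
                        vals[i, j] = cats[draws[i, j]]
        tables[name] = RatingTable(vals, kind="categorical", categories=cats)
    return tables
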