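"""Micron-calibrated measurements on the reconstructed canvas.

The pathologist draws labeled polygons (tumor_bed, invasive, cis) and
ruler segments in level-0 canvas pixels; everything here converts those
to physical units through the slide's microns-per-pixel calibration:
``mm = px * mpp / 1000`` and ``mm^2 = px_area * (mpp / 1000)^2``.

Tumor-bed size is the standard bidimensional measurement: the longest
diameter of the (union of) tumor-bed polygons, and the extent measured
perpendicular to that axis.  Residual-carcinoma percentages are area
ratios of the drawn labels: how finely invasive regions are outlined is
the user's cellularity judgement.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from shapely.geometry import MultiPolygon, Polygon, mapping, shape
from shapely.ops import unary_union
from shapely.validation import explain_validity

from .errors import MissingLabelError

__all__ = [
    "RulerSegment",
    "AnnotationSet",
    "TumorBedMetrics",
    "ruler_length",
    "polygon_area_mm2",
    "tumor_bed_diameters",
    "cancer_percentages",
    "load_annotations",
    "save_annotations",
]

LABELS = ("tumor_bed", "invasive", "cis")


@dataclass
class RulerSegment:
    """A two-point ruler measurement on the canvas."""

    p1: tuple[float, float]
    p2: tuple[float, float]
    mpp: float

    @property
    def length_mm(self) -> float:
        return ruler_length(self.p1, self.p2, self.mpp)


@dataclass
class AnnotationSet:
    """Labeled polygons in level-0 canvas pixels.

    ``features`` is a list of ``(polygon, label)`` with labels from the
    fixed vocabulary {tumor_bed, invasive, cis}.
    """

    features: list[tuple[Polygon, str]]
    mpp: float

    def __post_init__(self) -> None:
        for poly, label in self.features:
            if label not in LABELS:
                raise ValueError(f"unknown label {label!r}; expected one of {LABELS}")
            _validate_polygon(poly)
        if not self.mpp > 0:
            raise ValueError("mpp must be positive")

    def union(self, label: str) -> Polygon | MultiPolygon:
        geoms = [p for p, lb in self.features if lb == label]
        if not geoms:
            return Polygon()
        return unary_union(geoms)


@dataclass
class TumorBedMetrics:
    """Bed diameters (mm) and label-area carcinoma percentages."""

    length_mm: float
    width_mm: float
    pct_ca: float
    pct_cis: float


def _validate_polygon(poly: Polygon) -> None:
    if not isinstance(poly, (Polygon,)):
        raise ValueError("annotation features must be polygons")
    if len(poly.exterior.coords) < 4:  # closed ring: first == last
        raise ValueError("polygon ring needs at least 3 distinct vertices")
    if not poly.is_valid:
        raise ValueError(f"invalid polygon: {explain_validity(poly)}")


def _as_polygon(polygon) -> Polygon:
    if isinstance(polygon, Polygon):
        poly = polygon
    else:
        ring = list(polygon)
        if len(ring) < 3:
            raise ValueError("a polygon needs at least 3 vertices")
        poly = Polygon(ring)
    _validate_polygon(poly)
    return poly


def ruler_length(
    p1: Sequence[float], p2: Sequence[float], mpp: float
) -> float:
    """Euclidean distance between two canvas points, in millimetres."""
    if not mpp > 0:
        raise ValueError("mpp must be positive")
    coords = np.asarray([*p1, *p2], dtype=float)
    if not np.isfinite(coords).all():
        raise ValueError("ruler endpoints must be finite")
    d_px = math.hypot(p2[0] - p1[0], p2[1] - p1[1])
    return d_px * mpp / 1000.0


def polygon_area_mm2(polygon, mpp: float) -> float:
    """Area of a simple polygon (holes subtracted), in square millimetres."""
    if not mpp > 0:
        raise ValueError("mpp must be positive")
    poly = _as_polygon(polygon)
    return poly.area * (mpp / 1000.0) ** 2


def _hull_points(geom) -> np.ndarray:
    hull = geom.convex_hull
    if hull.is_empty:
        return np.empty((0, 2))
    if hull.geom_type == "Point":
        return np.asarray(hull.coords)
    if hull.geom_type == "LineString":
        return np.asarray(hull.coords)
    return np.asarray(hull.exterior.coords[:-1])


def tumor_bed_diameters(annotations: AnnotationSet) -> tuple[float, float]:
    """Longest bed diameter and the perpendicular extent, both in mm.

    Disjoint tumor_bed polygons are treated as one bed (their union): the
    reconstruction is of a single largest cross-section, so the length
    may span fragments.  Length is the maximum pairwise distance between
    convex-hull vertices; width is the extent of the hull projected onto
    the axis perpendicular to the length direction.
    """
    bed = annotations.union("tumor_bed")
    if bed.is_empty:
        raise MissingLabelError("no tumor_bed annotation present")
    pts = _hull_points(bed)
    scale = annotations.mpp / 1000.0
    if len(pts) == 1:
        return 0.0, 0.0
    # all-pairs on the hull: hull vertex counts are tiny after annotation
    diff = pts[:, None, :] - pts[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    length_px = math.sqrt(d2[i, j])
    if length_px == 0:
        return 0.0, 0.0
    axis = (pts[j] - pts[i]) / length_px
    perp = np.array([-axis[1], axis[0]])
    proj = pts @ perp
    width_px = float(proj.max() - proj.min())
    return length_px * scale, width_px * scale


def cancer_percentages(
    annotations: AnnotationSet, pct_cis_denominator: str = "carcinoma"
) -> tuple[float, float]:
    """Percent of the bed that is carcinoma, and percent of carcinoma that
    is in situ.

    Areas are unions clipped to the bed, so overlapping or nested labels
    never push a percentage past 100.  Carcinoma drawn outside the bed is
    excluded and reported in a warning.  ``pct_cis_denominator`` may be
    ``"carcinoma"`` (share of the carcinoma that is in situ — the usual
    residual-cancer-burden convention) or ``"bed"``.
    """
    if pct_cis_denominator not in ("carcinoma", "bed"):
        raise ValueError("pct_cis_denominator must be 'carcinoma' or 'bed'")
    bed = annotations.union("tumor_bed")
    if bed.is_empty:
        raise MissingLabelError("no tumor_bed annotation present")
    inv = annotations.union("invasive")
    cis = annotations.union("cis")

    inv_in = inv.intersection(bed)
    cis_in = cis.intersection(bed)
    outside = (inv.area - inv_in.area) + (cis.area - cis_in.area)
    if outside > 1e-9 * max(bed.area, 1.0):
        warnings.warn(
            f"{outside * (annotations.mpp / 1000.0) ** 2:.3g} mm^2 of carcinoma "
            "annotation lies outside the tumor bed and was excluded",
            stacklevel=2,
        )

    a_bed = bed.area
    a_inv = inv_in.area
    a_cis = cis_in.area
    a_ca = unary_union([inv_in, cis_in]).area  # avoid double counting overlap
    pct_ca = 100.0 * a_ca / a_bed if a_bed > 0 else 0.0
    if pct_cis_denominator == "carcinoma":
        pct_cis = 100.0 * a_cis / a_ca if a_ca > 0 else 0.0
    else:
        pct_cis = 100.0 * a_cis / a_bed if a_bed > 0 else 0.0
    return min(pct_ca, 100.0), min(pct_cis, 100.0)


def bed_metrics(
    annotations: AnnotationSet, pct_cis_denominator: str = "carcinoma"
) -> TumorBedMetrics:
    """Convenience: diameters plus percentages in one record."""
    length, width = tumor_bed_diameters(annotations)
    pct_ca, pct_cis = cancer_percentages(annotations, pct_cis_denominator)
    return TumorBedMetrics(length, width, pct_ca, pct_cis)


def save_annotations(annotations: AnnotationSet, path: str) -> str:
    """Write annotations as a GeoJSON FeatureCollection (px coordinates)."""
    doc = {
        "type": "FeatureCollection",
        "mpp": annotations.mpp,
        "features": [
            {
                "type": "Feature",
                "properties": {"label": label},
                "geometry": mapping(poly),
            }
            for poly, label in annotations.features
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)
    return path


def load_annotations(path: str, mpp: float | None = None) -> AnnotationSet:
    """Read a GeoJSON FeatureCollection of labeled polygons.

    mpp comes from the file's top-level ``mpp`` member unless overridden.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path!r} is not a GeoJSON FeatureCollection")
    resolved = mpp if mpp is not None else doc.get("mpp")
    if resolved is None:
        raise ValueError(f"no mpp in {path!r} and no override given")
    features = []
    for feat in doc.get("features", []):
        label = feat.get("properties", {}).get("label")
        geom = shape(feat["geometry"])
        if geom.geom_type == "MultiPolygon":
            for g in geom.geoms:
                features.append((g, label))
        else:
            features.append((geom, label))
    return AnnotationSet(features=features, mpp=float(resolved))
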