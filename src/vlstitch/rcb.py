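"""Residual Cancer Burden (RCB) scoring and post-therapy size staging.

The RCB index summarizes residual disease after neoadjuvant therapy from
the primary tumor bed and the axillary nodes:

    d_prim  = sqrt(d1 * d2)                      primary size (mm)
    f_inv   = (pct_ca/100) * (1 - pct_cis/100)   invasive cellularity fraction
    RCB     = 1.4 * (f_inv * d_prim)**0.17
            + (4 * (1 - 0.75**LN) * d_met)**0.17

with LN the number of positive lymph nodes and d_met the largest nodal
metastasis diameter (mm).  Each term is zero when its base is zero.  The
score is banded into grades: 0 (pathologic complete response), I
(0 < RCB <= 1.36), II (1.36 < RCB <= 3.28), III (RCB > 3.28).

ypT size staging uses the longest tumor-bed diameter: T1 <= 20 mm,
T2 20-50 mm (50 inclusive), T3 > 50 mm.  T4 depends on chest-wall/skin
involvement, a clinical finding outside size-based staging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import NotStageableError

__all__ = ["RcbInput", "RcbResult", "rcb_index", "rcb_grade", "t_stage"]

#: Upper band edges of grades I and II, inclusive.
GRADE_I_MAX = 1.36
GRADE_II_MAX = 3.28

#: Size-stage band edges (mm), inclusive on the upper side.
T1_MAX_MM = 20.0
T2_MAX_MM = 50.0


@dataclass
class RcbInput:
    """Measurements feeding the RCB index.

    d1_mm/d2_mm: tumor-bed length and width; pct_ca: percent of the bed
    that is residual carcinoma; pct_cis: percent of that carcinoma that
    is in situ; n_pos_nodes and d_met_mm describe nodal disease.
    """

    d1_mm: float
    d2_mm: float
    pct_ca: float
    pct_cis: float
    n_pos_nodes: int = 0
    d_met_mm: float = 0.0

    def __post_init__(self) -> None:
        for name in ("d1_mm", "d2_mm", "pct_ca", "pct_cis", "d_met_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_pos_nodes < 0:
            raise ValueError("n_pos_nodes must be non-negative")
        if self.pct_ca > 100 or self.pct_cis > 100:
            raise ValueError("percentages cannot exceed 100")
        if self.n_pos_nodes > 0 and not self.d_met_mm > 0:
            raise ValueError(
                "positive nodes recorded but largest metastasis diameter is 0"
            )
        if self.n_pos_nodes == 0 and self.d_met_mm > 0:
            raise ValueError(
                "metastasis diameter recorded with zero positive nodes"
            )


@dataclass
class RcbResult:
    """RCB score with its audit trail: both terms, the derived primary
    size and invasive fraction, the grade band and the ypT size stage."""

    d_prim_mm: float
    f_inv: float
    primary_term: float
    nodal_term: float
    score: float
    grade: str
    t_stage: str
    size_mode: str


def _primary_size(d1: float, d2: float, size_mode: str) -> float:
    if size_mode == "geometric_mean":
        return math.sqrt(d1 * d2)
    if size_mode == "longest":
        return max(d1, d2)
    raise ValueError("size_mode must be 'geometric_mean' or 'longest'")


def rcb_index(inp: RcbInput, size_mode: str = "geometric_mean") -> RcbResult:
    """Compute the RCB score, grade and ypT stage for one case.

    ``size_mode`` selects how the two bed diameters combine into the
    primary size: ``geometric_mean`` (sqrt(d1*d2), the standard
    bidimensional definition) or ``longest``.
    """
    d_prim = _primary_size(inp.d1_mm, inp.d2_mm, size_mode)
    f_inv = (inp.pct_ca / 100.0) * (1.0 - inp.pct_cis / 100.0)

    prim_base = f_inv * d_prim
    primary_term = 1.4 * prim_base**0.17 if prim_base > 0 else 0.0
    nodal_base = 4.0 * (1.0 - 0.75**inp.n_pos_nodes) * inp.d_met_mm
    nodal_term = nodal_base**0.17 if nodal_base > 0 else 0.0
    score = primary_term + nodal_term
    return RcbResult(
        d_prim_mm=d_prim,
        f_inv=f_inv,
        primary_term=primary_term,
        nodal_term=nodal_term,
        score=score,
        grade=rcb_grade(score),
        t_stage=t_stage(max(inp.d1_mm, inp.d2_mm)),
        size_mode=size_mode,
    )


def rcb_grade(score: float) -> str:
    """Band an RCB score into grade 0, I, II or III (upper edges
    inclusive: 1.36 is still grade I, 3.28 still grade II)."""
    if score < 0:
        raise ValueError("RCB score cannot be negative")
    if score == 0:
        return "0"
    if score <= GRADE_I_MAX:
        return "I"
    if score <= GRADE_II_MAX:
        return "II"
    return "III"


def t_stage(longest_diameter_mm: float, skin_chest_wall: bool = False) -> str:
    """Size-based ypT stage: T1 (<=20 mm), T2 (20-50 mm], T3 (>50 mm).

    ``skin_chest_wall=True`` signals T4 disease, which is not determined
    by size; it raises :class:`NotStageableError` rather than guessing.
    """
    if skin_chest_wall:
        raise NotStageableError(
            "chest-wall/skin involvement implies T4, which is not a "
            "size-based stage"
        )
    if longest_diameter_mm < 0:
        raise ValueError("diameter cannot be negative")
    if longest_diameter_mm <= T1_MAX_MM:
        return "T1"
    if longest_diameter_mm <= T2_MAX_MM:
        return "T2"
    return "T3"
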