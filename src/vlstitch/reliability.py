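"""Inter-rater reliability statistics for multi-reader panels.

A complete subjects x raters table is rated either on a continuous scale
(diameters, percentages, RCB index) or categorically (RCB grade, ypT
stage).  Consistency of continuous measurements is summarized by the
intraclass correlation coefficient under the two-way random-effects,
absolute-agreement, single-measures model — ICC(2,1) in the
Shrout-Fleiss taxonomy — which treats the raters as a random sample of
interchangeable readers and penalizes systematic rater offsets:

    ICC(2,1) = (MS_R - MS_E) /
               (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

from the two-way ANOVA mean squares (rows = subjects, columns = raters).
Categorical concordance uses Fleiss' kappa, and paired timing
comparisons use the paired-samples t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateStatisticError

__all__ = ["RatingTable", "icc", "fleiss_kappa", "paired_t", "PairedTResult"]


@dataclass
class RatingTable:
    """n_subjects x k_raters matrix of ratings with no missing cells."""

    values: np.ndarray
    kind: str = "continuous"
    categories: tuple | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("rating table must be 2-D (subjects x raters)")
        n, k = v.shape
        if n < 2 or k < 2:
            raise ValueError("need at least 2 subjects and 2 raters")
        if self.kind == "continuous":
            v = v.astype(float)
            if not np.isfinite(v).all():
                raise ValueError("continuous table contains non-finite cells")
        elif self.kind == "categorical":
            if self.categories is None:
                self.categories = tuple(sorted(set(v.ravel().tolist())))
        else:
            raise ValueError("kind must be 'continuous' or 'categorical'")
        self.values = v

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def k_raters(self) -> int:
        return self.values.shape[1]


def icc(table: RatingTable) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measures."""
    if table.kind != "continuous":
        raise ValueError("ICC requires a continuous rating table")
    x = table.values
    n, k = x.shape
    grand = x.mean()
    if np.allclose(x, grand):
        raise DegenerateStatisticError("ICC undefined: table has zero variance")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if denom == 0:
        raise DegenerateStatisticError("ICC undefined: zero denominator")
    return float((ms_r - ms_e) / denom)


def fleiss_kappa(table: RatingTable) -> float:
    """Fleiss' kappa for k raters assigning n subjects to categories.

    kappa = (P_bar - Pe_bar) / (1 - Pe_bar), with per-subject agreement
    P_i = (sum_j n_ij^2 - k) / (k (k-1)) and chance agreement
    Pe_bar = sum_j p_j^2 over the marginal category proportions.
    """
    if table.kind != "categorical":
        raise ValueError("Fleiss' kappa requires a categorical rating table")
    x = table.values
    n, k = x.shape
    cats = list(table.categories)
    counts = np.zeros((n, len(cats)), dtype=float)
    for j, c in enumerate(cats):
        counts[:, j] = (x == c).sum(axis=1)
    p_j = counts.sum(axis=0) / (n * k)
    pe = float((p_j**2).sum())
    if pe >= 1.0:
        raise DegenerateStatisticError(
            "kappa undefined: every rating is the same category"
        )
    p_i = ((counts**2).sum(axis=1) - k) / (k * (k - 1))
    return float((p_i.mean() - pe) / (1.0 - pe))


@dataclass
class PairedTResult:
    t: float
    df: int
    p: float


def paired_t(x: Sequence[float], y: Sequence[float]) -> PairedTResult:
    """Two-sided paired-samples t-test on matched vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired t-test needs two equal-length vectors")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateStatisticError(
            "paired t-test undefined: differences have zero variance"
        )
    t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return PairedTResult(t=float(t), df=df, p=float(p))


def table_from_csv(path: str, kind: str) -> RatingTable:
    """Load a ratings CSV: first column subject id, remaining columns raters."""
    import csv

    rows = []
    with open(path) as fh:
        reader = csv.reader(fh)
        header = next(reader)
        for rec in reader:
            rows.append(rec[1:])
    if kind == "continuous":
        values = np.asarray(rows, dtype=float)
    else:
        values = np.asarray(rows, dtype=object)
    return RatingTable(values=values, kind=kind)
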