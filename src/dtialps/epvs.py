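"""ePVS burden grading, QRISK3 risk bands, and inter-rater agreement.

Enlarged perivascular spaces are counted on the slice with the greatest
burden in each of two regions (basal ganglia, centrum semiovale) and mapped
to a semi-quantitative 0-4 grade.  Rater agreement on the ordinal grades is
summarized with unweighted Cohen's kappa and its large-sample confidence
interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "EPVSRating",
    "AgreementResult",
    "grade_epvs",
    "qrisk_category",
    "cohens_kappa",
    "GRADE_BINS",
]

EPVS_REGIONS = ("basal_ganglia", "centrum_semiovale")

# grade g covers counts in [GRADE_BINS[g], GRADE_BINS[g+1])
GRADE_BINS = (0, 1, 11, 21, 41)


@dataclass(frozen=True)
class EPVSRating:
    """One rater's count and derived grade for one region of one subject."""

    region: str
    count: int
    rater: str = ""

    def __post_init__(self) -> None:
        if self.region not in EPVS_REGIONS:
            raise ValueError(f"region must be one of {EPVS_REGIONS}")
        object.__setattr__(self, "count", _check_count(self.count))

    @property
    def grade(self) -> int:
        return int(grade_epvs(self.count))


def _check_count(count):
    arr = np.asarray(count)
    if arr.dtype == bool or not np.issubdtype(arr.dtype, np.number):
        raise ValueError("count must be numeric")
    if np.any(arr != np.floor(arr)):
        raise ValueError("count must be an integer")
    if np.any(arr < 0):
        raise ValueError("count must be non-negative")
    return count if np.ndim(count) else int(arr)


def grade_epvs(count):
    """Semi-quantitative ePVS grade from a region count.

    0: no visible ePVS; 1: 1-10; 2: 11-20; 3: 21-40; 4: >= 41.
    Accepts scalars or integer arrays.
    """
    count = _check_count(count)
    grade = np.digitize(count, GRADE_BINS[1:], right=False)
    return int(grade) if np.ndim(count) == 0 else grade


def qrisk_category(score: float) -> str:
    """QRISK3 10-year risk band: low (<=10%), moderate (10.1-20%), high (>=20.1%).

    The printed bands leave (10, 10.1) unassigned; scores there are closed
    upward into 'moderate'.
    """
    score = float(score)
    if not np.isfinite(score) or score < 0:
        raise ValueError("QRISK3 score must be a non-negative percentage")
    if score <= 10.0:
        return "low"
    if score <= 20.0:
        return "moderate"
    return "high"


@dataclass(frozen=True)
class AgreementResult:
    """Cohen's kappa with a large-sample confidence interval."""

    kappa: float
    ci_low: float
    ci_high: float
    n_items: int


def cohens_kappa(ratings_a, ratings_b, ci_level: float = 0.95) -> AgreementResult:
    """Unweighted Cohen's kappa between two raters' categorical sequences.

    kappa = (p_o - p_e) / (1 - p_e), with the standard large-sample standard
    error sqrt(p_o (1 - p_o) / (n (1 - p_e)^2)).  If both raters use a single
    shared category throughout (p_e = 1 with perfect agreement), kappa is
    defined as 1 with a degenerate interval.
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("ratings must be equal-length 1-D sequences")
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rated items")

    cats, a_idx = np.unique(a, return_inverse=True)
    cats_b, b_idx = np.unique(b, return_inverse=True)
    all_cats = np.unique(np.concatenate([cats, cats_b]))
    a_idx = np.searchsorted(all_cats, a)
    b_idx = np.searchsorted(all_cats, b)
    k = all_cats.shape[0]

    table = np.zeros((k, k))
    np.add.at(table, (a_idx, b_idx), 1.0)
    p_o = np.trace(table) / n
    p_e = float(np.sum(table.sum(axis=1) * table.sum(axis=0)) / n**2)

    if p_e >= 1.0:
        return AgreementResult(kappa=1.0, ci_low=1.0, ci_high=1.0, n_items=n)

    kappa = (p_o - p_e) / (1.0 - p_e)
    se = np.sqrt(p_o * (1.0 - p_o) / (n * (1.0 - p_e) ** 2))
    z = sps.norm.ppf(0.5 + ci_level / 2.0)
    lo = max(kappa - z * se, -1.0)
    hi = min(kappa + z * se, 1.0)
    return AgreementResult(kappa=float(kappa), ci_low=float(lo), ci_high=float(hi), n_items=n)
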