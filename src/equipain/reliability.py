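"""Inter-observer agreement: two-way random-effects absolute-agreement ICC.

ICC(2, A1) — single-rater, absolute agreement, raters treated as a random
sample — from the two-way ANOVA decomposition of a subjects x raters grid:

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n) (MSC - MSE))

with MSR/MSC/MSE the row (subject), column (rater) and residual mean
squares.  The 95% confidence interval follows the McGraw-Wong F-distribution
construction with a Satterthwaite denominator df.  Estimates are labelled
poor (<0.5), moderate (0.5-0.75), good (0.75-0.9) or excellent (>=0.9).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (DegenerateVarianceError, InsufficientDataError,
                         ValidationError)

__all__ = [
    "RatingsMatrix",
    "ICCResult",
    "build_ratings_matrix",
    "icc_agreement",
    "classify_reliability",
    "icc_by_scale",
]

RELIABILITY_THRESHOLDS = (0.5, 0.75, 0.9)  # poor | moderate | good | excellent


@dataclass
class RatingsMatrix:
    """Subjects x raters total scores; one subject = one assessment event."""

    values: np.ndarray  # (n_subjects, k_raters), NaN = missing
    scale: str = ""
    rater_ids: Optional[Sequence[str]] = None

    def complete_cases(self) -> np.ndarray:
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[1] < 2:
            raise ValidationError("ratings matrix must be 2-D with >= 2 raters")
        return v[~np.isnan(v).any(axis=1)]


@dataclass
class ICCResult:
    estimate: float
    ci_low: float
    ci_high: float
    msr: float
    msc: float
    mse: float
    n_subjects: int
    k_raters: int
    label: str


def _anova_mean_squares(x: np.ndarray) -> Tuple[float, float, float]:
    """Two-way (subject x rater) ANOVA mean squares for a complete grid."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc_agreement(matrix: RatingsMatrix, alpha: float = 0.05) -> ICCResult:
    """ICC(2, A1) with a 95% (1 - alpha) confidence interval.

    Missing ratings are handled by complete-case deletion; at least 5
    complete subjects are required.  A grid with zero total variance raises
    ``DegenerateVarianceError``.
    """
    x = matrix.complete_cases()
    n, k = x.shape
    if n < 5:
        raise InsufficientDataError(
            f"only {n} complete cases after missing-data handling; >= 5 required"
        )
    if np.ptp(x) == 0:
        raise DegenerateVarianceError("all ratings identical: ICC undefined")
    msr, msc, mse = _anova_mean_squares(x)

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0:
        raise DegenerateVarianceError("non-positive ICC denominator")
    icc = (msr - mse) / denom

    ci_low, ci_high = _mcgraw_wong_ci(icc, msr, msc, mse, n, k, alpha)
    ci_low = min(ci_low, icc)
    ci_high = max(ci_high, icc)
    return ICCResult(
        estimate=float(icc), ci_low=float(ci_low), ci_high=float(ci_high),
        msr=msr, msc=msc, mse=mse, n_subjects=n, k_raters=k,
        label=classify_reliability(icc),
    )


def _mcgraw_wong_ci(icc: float, msr: float, msc: float, mse: float,
                    n: int, k: int, alpha: float) -> Tuple[float, float]:
    """F-based interval for ICC(A,1) with Satterthwaite denominator df."""
    a = (k * icc) / (n * (1.0 - icc)) if icc < 1 else np.inf
    b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1 else np.inf
    if not np.isfinite(a):
        return 1.0, 1.0
    num = (a * msc + b * mse) ** 2
    den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num / den if den > 0 else (n - 1) * (k - 1)
    f_u = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
    f_l = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
    lower = n * (msr - f_u * mse) / (
        f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_l * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_l * msr)
    return float(np.clip(lower, -1.0, 1.0)), float(np.clip(upper, -1.0, 1.0))


def classify_reliability(estimate: float,
                         thresholds: Tuple[float, float, float] = RELIABILITY_THRESHOLDS
                         ) -> str:
    """Categorize an ICC estimate (poor / moderate / good / excellent)."""
    if estimate > 1.0 + 1e-12:
        raise ValidationError(f"ICC estimate {estimate} exceeds 1")
    lo, mid, hi = thresholds
    if estimate < lo:
        return "poor"
    if estimate < mid:
        return "moderate"
    if estimate < hi:
        return "good"
    return "excellent"


def build_ratings_matrix(assessments: pd.DataFrame, scale: str,
                         fixed_raters: Sequence[str] = ("1", "2"),
                         pool_third: bool = True) -> RatingsMatrix:
    """Pivot long-format assessments into a subjects x raters grid.

    One subject is one (horse, occasion, timing) assessment event.  With
    ``pool_third`` (the default, mirroring a rotating-third-observer design)
    every observer outside ``fixed_raters`` is pooled into a single third
    rater column; with ``pool_third=False`` each observer keeps its own
    column and complete-case deletion applies across all of them.
    """
    req = {"horse", "occasion", "observer", "scale", "timing", "total"}
    if not req <= set(assessments.columns):
        raise ValidationError(f"need columns {sorted(req)}")
    sub = assessments[assessments["scale"] == scale].copy()
    if sub.empty:
        raise InsufficientDataError(f"no assessments for scale {scale!r}")
    sub["observer"] = sub["observer"].astype(str)
    if pool_third:
        sub["rater"] = np.where(sub["observer"].isin(list(fixed_raters)),
                                sub["observer"], "third")
    else:
        sub["rater"] = sub["observer"]
    wide = sub.pivot_table(index=["horse", "occasion", "timing"],
                           columns="rater", values="total", aggfunc="first")
    return RatingsMatrix(values=wide.to_numpy(float), scale=scale,
                         rater_ids=list(wide.columns))


def icc_by_scale(assessments: pd.DataFrame, scales: Sequence[str],
                 pool_third: bool = True) -> pd.DataFrame:
    """Per-scale ICC table: ``scale,icc,ci_low,ci_high,label,n,k``."""
    rows = []
    for scale in scales:
        res = icc_agreement(build_ratings_matrix(assessments, scale,
                                                 pool_third=pool_third))
        rows.append({"scale": scale, "icc": res.estimate,
                     "ci_low": res.ci_low, "ci_high": res.ci_high,
                     "label": res.label, "n": res.n_subjects, "k": res.k_raters})
    return pd.DataFrame(rows)
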