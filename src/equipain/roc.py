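"""ROC curves, AUC with DeLong confidence intervals, accuracy labels.

AUC is computed as the Mann-Whitney probability that a randomly chosen
positive ("pain") observation receives a higher prediction than a randomly
chosen negative one, with ties counted 1/2 — identical to the trapezoid area
under the empirical ROC curve.  The 95% CI uses the DeLong structural-
components variance with a normal approximation, clipped to [0, 1].
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np
from scipy import stats

from .exceptions import UndefinedROCError, ValidationError

__all__ = [
    "ROCCurve",
    "compute_roc",
    "auc_ci",
    "classify_auc",
    "AUC_BANDS",
]

# (upper edge, label); "good" anchored at 0.72 per the qualitative convention
# that AUC > 0.72 marks good diagnostic accuracy
AUC_BANDS: Tuple[Tuple[float, str], ...] = (
    (0.5, "no_discrimination"),
    (0.72, "poor"),
    (0.8, "good"),
    (0.9, "excellent"),
    (1.0 + 1e-12, "outstanding"),
)


@dataclass
class ROCCurve:
    thresholds: np.ndarray  # decreasing; predictions >= threshold are "pain"
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    label: str = ""


def _check_inputs(predictions, labels) -> Tuple[np.ndarray, np.ndarray]:
    p = np.asarray(predictions, float)
    y = np.asarray(labels)
    if p.shape != y.shape or p.ndim != 1:
        raise ValidationError("predictions and labels must be equal-length 1-D")
    if not np.all(np.isfinite(p)):
        raise ValidationError("predictions must be finite")
    y = y.astype(bool)
    if y.all() or not y.any():
        raise UndefinedROCError("ROC undefined with a single class present")
    return p, y


def _mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """P(pos > neg) + 0.5 P(pos == neg) via midranks."""
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    n_pos, n_neg = len(pos), len(neg)
    return float((ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def compute_roc(predictions: Sequence[float], labels: Sequence[int],
                with_ci: bool = True) -> ROCCurve:
    """Empirical ROC over all distinct prediction thresholds."""
    p, y = _check_inputs(predictions, labels)
    pos, neg = p[y], p[~y]
    n_pos, n_neg = len(pos), len(neg)

    thresholds = np.concatenate([[np.inf], np.unique(p)[::-1]])
    sens = np.array([(pos >= th).mean() for th in thresholds])
    spec = np.array([(neg < th).mean() for th in thresholds])
    auc = _mann_whitney_auc(pos, neg)

    curve = ROCCurve(thresholds=thresholds, sensitivity=sens, specificity=spec,
                     auc=auc, n_pos=n_pos, n_neg=n_neg,
                     label=classify_auc(auc))
    if with_ci and n_pos >= 2 and n_neg >= 2:
        curve.ci_low, curve.ci_high = auc_ci(curve, p, y)
    return curve


def auc_ci(curve: ROCCurve, predictions: Sequence[float], labels: Sequence[int],
           alpha: float = 0.05) -> Tuple[float, float]:
    """DeLong normal-approximation CI for the AUC, clipped to [0, 1]."""
    p, y = _check_inputs(predictions, labels)
    pos, neg = p[y], p[~y]
    n_pos, n_neg = len(pos), len(neg)
    if n_pos < 2 or n_neg < 2:
        raise ValidationError("DeLong CI needs >= 2 observations per class")

    # structural components: for each positive, the fraction of negatives it
    # outranks (ties 1/2), and symmetrically for negatives
    diff = pos[:, None] - neg[None, :]
    cmp_ = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    v10 = cmp_.mean(axis=1)
    v01 = cmp_.mean(axis=0)
    var = v10.var(ddof=1) / n_pos + v01.var(ddof=1) / n_neg
    if var <= 0:
        warnings.warn("degenerate DeLong variance: CI collapses to the point AUC")
        return curve.auc, curve.auc
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    half = z * np.sqrt(var)
    return (float(np.clip(curve.auc - half, 0.0, 1.0)),
            float(np.clip(curve.auc + half, 0.0, 1.0)))


def classify_auc(auc: float,
                 bands: Tuple[Tuple[float, str], ...] = AUC_BANDS) -> str:
    """Diagnostic-accuracy label for an AUC (bands configurable).

    The first band is inclusive of its upper edge (AUC <= 0.5 means chance
    cannot be beaten); later bands are half-open ``[lower, upper)``.
    """
    if not 0.0 <= auc <= 1.0:
        raise ValidationError(f"AUC must be in [0, 1], got {auc}")
    first_upper, first_label = bands[0]
    if auc <= first_upper:
        return first_label
    for upper, label in bands[1:]:
        if auc < upper:
            return label
    return bands[-1][1]
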