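"""Structural model of the four equine pain scales and score summaries.

The four scales — HGS (facial grimace), EQUUS-FAP (facial), EPS (mixed
facial/behavioural) and CPS (composite orthopedic) — are represented by
their total-score ranges (0-12, 0-18, 0-30, 0-39) and observation times
(2, 2, 2, 5 minutes).  Item-level wording belongs to the original scale
publications and is not reproduced; the analysis consumes total scores only,
with optional user-supplied item lists validated against the total range.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, ValidationError

__all__ = [
    "ScaleDefinition",
    "PainAssessment",
    "builtin_scales",
    "get_scale",
    "validate_and_total",
    "percent_of_max",
    "summarize_scores",
]

SCALE_ORDER = ["HGS", "EQUUS-FAP", "EPS", "CPS"]  # fixed assessment order


@dataclass(frozen=True)
class ScaleDefinition:
    """A pain scale's scoring range and observation protocol."""

    name: str
    total_max: int
    observation_minutes: int
    total_min: int = 0
    items: Optional[Tuple[Tuple[str, int, int], ...]] = None  # (name, min, max)

    def validate(self) -> None:
        if self.total_max <= self.total_min:
            raise ConfigurationError(f"{self.name}: total_max must exceed total_min")
        if self.items is not None:
            if sum(mx for _, _, mx in self.items) != self.total_max:
                raise ConfigurationError(
                    f"{self.name}: item maxima must sum to total_max {self.total_max}"
                )


@dataclass
class PainAssessment:
    """One observer x scale x occasion total pain score."""

    horse_id: str
    occasion_id: str
    observer_id: str
    scale: str
    total_score: int
    timing: str  # before_gait | after_gait
    phase: str  # pre_induction | post_induction
    item_scores: Optional[Dict[str, int]] = None


def builtin_scales() -> List[ScaleDefinition]:
    """The four scales with their published total ranges and observation times."""
    return [
        ScaleDefinition("HGS", total_max=12, observation_minutes=2),
        ScaleDefinition("EQUUS-FAP", total_max=18, observation_minutes=2),
        ScaleDefinition("EPS", total_max=30, observation_minutes=2),
        ScaleDefinition("CPS", total_max=39, observation_minutes=5),
    ]


def get_scale(name: str) -> ScaleDefinition:
    for s in builtin_scales():
        if s.name == name:
            return s
    raise ConfigurationError(f"unknown pain scale {name!r}; known: {SCALE_ORDER}")


def validate_and_total(assessment: PainAssessment,
                       scale: ScaleDefinition) -> PainAssessment:
    """Range-check a score; compute the total from items when present."""
    if assessment.scale != scale.name:
        raise ValidationError(
            f"scale mismatch: assessment is {assessment.scale!r}, definition {scale.name!r}"
        )
    if assessment.item_scores is not None:
        if scale.items is not None:
            bounds = {n: (lo, hi) for n, lo, hi in scale.items}
            for item, val in assessment.item_scores.items():
                if item not in bounds:
                    raise ValidationError(f"{scale.name}: unknown item {item!r}")
                lo, hi = bounds[item]
                if not lo <= val <= hi:
                    raise ValidationError(
                        f"{scale.name}: item {item!r} score {val} outside [{lo}, {hi}]"
                    )
        assessment.total_score = int(sum(assessment.item_scores.values()))
    total = assessment.total_score
    if not scale.total_min <= total <= scale.total_max:
        raise ValidationError(
            f"{scale.name}: total_score {total} outside "
            f"[{scale.total_min}, {scale.total_max}] "
            f"(horse={assessment.horse_id}, occasion={assessment.occasion_id}, "
            f"observer={assessment.observer_id})"
        )
    return assessment


def percent_of_max(total_score: float, scale: ScaleDefinition) -> float:
    """Score as a percentage of the scale maximum, to one decimal place."""
    if not scale.total_min <= total_score <= scale.total_max:
        raise ValidationError(
            f"{scale.name}: score {total_score} outside scale range"
        )
    return round(100.0 * total_score / scale.total_max, 1)


def summarize_scores(assessments: pd.DataFrame, by: str = "phase") -> pd.DataFrame:
    """Descriptive summary per scale x group: median, Q1-Q3, min, max.

    Quartiles use linear interpolation between order statistics.  A per-scale
    Shapiro-Wilk normality flag is included (``normal_p`` is NaN and
    ``normality`` is ``"n/a"`` on degenerate, e.g. constant, data).  Empty
    cells are reported as missing, never as silent zeros.
    """
    required = {"scale", "total", by}
    missing = required - set(assessments.columns)
    if missing:
        raise ValidationError(f"summary input missing columns {sorted(missing)}")

    rows = []
    scales_present = [s for s in SCALE_ORDER if s in set(assessments["scale"])]
    scales_present += sorted(set(assessments["scale"]) - set(SCALE_ORDER))
    groups = sorted(assessments[by].unique())
    for scale in scales_present:
        sub_scale = assessments[assessments["scale"] == scale]
        shapiro_p, normality = _shapiro_flag(sub_scale["total"].to_numpy(float))
        for g in groups:
            vals = sub_scale.loc[sub_scale[by] == g, "total"].to_numpy(float)
            if len(vals) == 0:
                rows.append({"scale": scale, by: g, "n": 0,
                             "median": np.nan, "q1": np.nan, "q3": np.nan,
                             "min": np.nan, "max": np.nan,
                             "normal_p": shapiro_p, "normality": normality})
                continue
            rows.append({
                "scale": scale, by: g, "n": int(len(vals)),
                "median": float(np.median(vals)),
                "q1": float(np.quantile(vals, 0.25)),
                "q3": float(np.quantile(vals, 0.75)),
                "min": float(vals.min()),
                "max": float(vals.max()),
                "normal_p": shapiro_p,
                "normality": normality,
            })
    return pd.DataFrame(rows)


def _shapiro_flag(vals: np.ndarray) -> Tuple[float, str]:
    if len(vals) < 3 or np.ptp(vals) == 0:
        return float("nan"), "n/a"
    with np.errstate(all="ignore"):
        p = float(stats.shapiro(vals).pvalue)
    return p, ("non_normal" if p < 0.05 else "normal")
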