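"""Proportional-time normalization and pain-status categorization.

Horses respond to induction on individual clocks, so each horse's occasion
series is remapped onto a proportional time scale: baseline at 0%, the
peak-asymmetry occasion at 50%, the last measurement at 100%, with other
occasions interpolated linearly in clock time within their segment.  A
TAS > 10 mm cut-off (a mild-lameness analogue) defines binary pain status.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "NormalizedOccasion",
    "assign_proportional_time",
    "classify_pain_status",
    "add_timeline_columns",
]

log = logging.getLogger(__name__)

DEFAULT_PAIN_CUTOFF_MM = 10.0


@dataclass
class NormalizedOccasion:
    horse_id: str
    occasion_id: str
    clock_time: float  # h
    tas: float  # mm
    prop_time: float  # percent, [0, 100]
    pain_status: bool


def classify_pain_status(tas: float, cutoff: float = DEFAULT_PAIN_CUTOFF_MM) -> bool:
    """Strict TAS > cutoff rule; TAS equal to the cutoff is 'free from pain'."""
    if tas < 0:
        raise ValidationError(f"tas must be >= 0, got {tas}")
    return tas > cutoff


def assign_proportional_time(occasions: pd.DataFrame,
                             cutoff: float = DEFAULT_PAIN_CUTOFF_MM) -> pd.DataFrame:
    """Map one horse's occasions onto the 0/50/100% proportional time scale.

    ``occasions`` needs columns ``horse``, ``occasion``, ``clock_time_h``,
    ``tas_mm``; the baseline is the (single) occasion with clock time <= 0.
    Ties in the maximum TAS resolve to the earliest occasion.  If the peak is
    the last occasion, the 50% anchor is placed one inter-occasion segment
    before it (logged); a peak at baseline is a degenerate-anchor error.
    """
    req = {"horse", "occasion", "clock_time_h", "tas_mm"}
    if not req <= set(occasions.columns):
        raise ValidationError(f"need columns {sorted(req)}")
    horses = occasions["horse"].unique()
    if len(horses) != 1:
        raise ValidationError("assign_proportional_time handles one horse at a time")
    df = occasions.sort_values("clock_time_h").reset_index(drop=True)
    if len(df) < 3:
        raise ValidationError("need >= 3 occasions including baseline")
    t = df["clock_time_h"].to_numpy(float)
    if len(np.unique(t)) != len(t):
        raise ValidationError("occasion clock times must be unique")
    tas = df["tas_mm"].to_numpy(float)
    if np.any(tas < 0):
        raise ValidationError("tas must be >= 0")

    base_mask = t <= 0
    if base_mask.sum() != 1:
        raise ValidationError("exactly one baseline occasion (clock time <= 0) required")
    t_base = t[0]
    peak_i = int(np.argmax(tas))  # argmax returns the earliest tie
    if peak_i == 0:
        raise ValidationError(
            f"degenerate anchors: peak TAS at baseline for horse {horses[0]}"
        )
    t_last = t[-1]
    if peak_i == len(df) - 1:
        seg = t[-1] - t[-2]
        t_peak = t_last - seg
        log.warning("horse %s: peak TAS at last occasion; 50%% anchor moved to "
                    "%.2f h (one segment before last)", horses[0], t_peak)
    else:
        t_peak = t[peak_i]

    anchors_t = np.array([t_base, t_peak, t_last], float)
    anchors_p = np.array([0.0, 50.0, 100.0])
    prop = np.interp(t, anchors_t, anchors_p)
    out = df.copy()
    out["prop_time_pct"] = prop
    out["pain_status"] = [classify_pain_status(v, cutoff) for v in tas]
    return out


def add_timeline_columns(occasions: pd.DataFrame,
                         cutoff: float = DEFAULT_PAIN_CUTOFF_MM) -> pd.DataFrame:
    """Apply proportional-time normalization horse by horse."""
    parts = [assign_proportional_time(g, cutoff)
             for _, g in occasions.groupby("horse", sort=True)]
    return pd.concat(parts, ignore_index=True)
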