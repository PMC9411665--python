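"""Vertical movement-asymmetry metrics from head and pelvis marker traces.

Impact lameness in the trotting horse shows up as a left/right difference in
how far the head and pelvis drop during the two stance phases of a stride.
This module segments a vertical displacement trace into strides, locates the
two minima per stride, and computes the standard asymmetry metrics:

* ``HDmin`` — trial-mean difference between head-marker minima in the two
  stance phases (mm),
* ``PDmin`` — the same for the pelvis marker (mm),
* ``TAS``   — Total Asymmetry Score, the change from baseline,
  ``|dHDmin|/2 + |dPDmin|`` (mm).

Stride segmentation: the pelvis oscillates twice per stride at trot, so the
dominant spectral peak sits at twice the stride frequency; we locate that
peak, halve it, validate the stride rate against the physiologic 1.0-2.5 Hz
band, low-pass filter at four times the stride rate (zero-phase Butterworth),
and detect local minima with a minimum separation of 0.3 stride periods and a
prominence of at least 20% of the median minimum prominence.  Minima are
refined to sub-sample accuracy by parabolic interpolation.  Minima alternate
between the two stance phases; the first detected minimum fixes the parity.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .exceptions import InsufficientDataError, SegmentationError, ValidationError

__all__ = [
    "MarkerTrace",
    "StrideSegmentation",
    "AsymmetryResult",
    "OccasionAsymmetry",
    "read_trace_tsv",
    "write_trace_tsv",
    "segment_strides",
    "compute_asymmetry",
    "compute_tas",
    "analyze_trial",
    "combine_trials",
]

STRIDE_BAND = (1.0, 2.5)  # Hz, admissible stride frequencies at trot


@dataclass
class MarkerTrace:
    """One trial's time-stamped vertical head/pelvis positions (mm)."""

    time: np.ndarray  # s, strictly increasing
    head_z: np.ndarray  # mm
    pelvis_z: np.ndarray  # mm
    sampling_rate: float  # Hz
    horse_id: str = ""
    occasion_id: str = ""

    def validate(self) -> None:
        t = np.asarray(self.time, float)
        if t.ndim != 1 or len(t) < 2:
            raise ValidationError("time: need a 1-D vector with >= 2 samples")
        if not np.all(np.diff(t) > 0):
            raise ValidationError("time: must be strictly increasing")
        for name in ("head_z", "pelvis_z"):
            z = np.asarray(getattr(self, name), float)
            if z.shape != t.shape:
                raise ValidationError(f"{name}: length must match time")
            if not np.all(np.isfinite(z)):
                raise ValidationError(f"{name}: missing or non-finite samples")
        fs_implied = (len(t) - 1) / (t[-1] - t[0])
        if abs(fs_implied - self.sampling_rate) > 0.01 * self.sampling_rate:
            raise ValidationError(
                f"sampling_rate {self.sampling_rate} Hz inconsistent with time "
                f"vector (implied {fs_implied:.2f} Hz)"
            )

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


@dataclass
class StrideSegmentation:
    """Stride boundaries and per-stride minima (sample indices).

    ``head_minima`` / ``pelvis_minima`` have shape (n_strides, 2): columns are
    the side-1 and side-2 stance minima of each stride.  ``*_values`` hold the
    parabolic-refined (filtered) displacement at those minima, mm.
    """

    boundaries: np.ndarray  # (n_strides + 1,) sample indices
    head_minima: np.ndarray
    pelvis_minima: np.ndarray
    head_values: np.ndarray
    pelvis_values: np.ndarray
    stride_frequency: float  # Hz


@dataclass
class AsymmetryResult:
    """Trial-mean HDmin / PDmin with the right-positive sign convention.

    Negative (left-side) trial means are reported as positive magnitudes, as
    is conventional for these metrics; the conversion is applied exactly once.
    """

    hdmin: float  # mm
    pdmin: float  # mm
    n_strides: int
    side_convention: str = "right_positive"
    hdmin_signed: float = 0.0  # pre-conversion trial mean, mm
    pdmin_signed: float = 0.0


@dataclass
class OccasionAsymmetry:
    horse_id: str
    occasion_id: str
    clock_time: float  # h since induction
    hdmin: float  # mm
    pdmin: float  # mm
    tas: float  # mm, vs the horse's baseline occasion
    n_strides: int


# ----------------------------------------------------------------- trace I/O

TRACE_COLUMNS = ["time_s", "head_z_mm", "pelvis_z_mm"]


def read_trace_tsv(path: str | Path, sampling_rate: Optional[float] = None,
                   horse_id: str = "", occasion_id: str = "") -> MarkerTrace:
    """Read a tab-separated trace file (``time_s  head_z_mm  pelvis_z_mm``)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing trace columns {missing}")
    t = df["time_s"].to_numpy(float)
    if sampling_rate is None:
        sampling_rate = (len(t) - 1) / (t[-1] - t[0])
    trace = MarkerTrace(
        time=t,
        head_z=df["head_z_mm"].to_numpy(float),
        pelvis_z=df["pelvis_z_mm"].to_numpy(float),
        sampling_rate=float(sampling_rate),
        horse_id=horse_id,
        occasion_id=occasion_id,
    )
    trace.validate()
    return trace


def write_trace_tsv(trace: MarkerTrace, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRACE_COLUMNS) + "\n")
        for t, h, p in zip(trace.time, trace.head_z, trace.pelvis_z):
            fh.write(f"{t:.6f}\t{h:.6f}\t{p:.6f}\n")


# ------------------------------------------------------------- segmentation

def _dominant_stride_frequency(z: np.ndarray, fs: float) -> float:
    """Stride frequency from the dominant double-frequency spectral peak."""
    z = z - z.mean()
    freqs, power = signal.periodogram(z, fs=fs, window="hann")
    lo, hi = 2.0 * STRIDE_BAND[0], 2.0 * STRIDE_BAND[1]
    band = (freqs >= lo) & (freqs <= hi)
    if not band.any() or power[band].max() <= 0:
        raise SegmentationError("no dominant periodicity in the trot band")
    f_dom = float(freqs[band][np.argmax(power[band])])
    # sanity: the peak must clearly dominate the broadband noise floor
    if power[band].max() < 20.0 * np.median(power[freqs > 0.5]):
        raise SegmentationError("no dominant periodicity in the trot band")
    f_stride = f_dom / 2.0
    if not STRIDE_BAND[0] <= f_stride <= STRIDE_BAND[1]:
        raise SegmentationError(
            f"estimated stride frequency {f_stride:.2f} Hz outside "
            f"{STRIDE_BAND[0]}-{STRIDE_BAND[1]} Hz"
        )
    return f_stride


def _lowpass(z: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    sos = signal.butter(4, min(cutoff, 0.45 * fs), btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, z)


def _refine_minimum(z: np.ndarray, idx: int) -> float:
    """Parabolic sub-sample refinement of the minimum value at sample idx."""
    if idx <= 0 or idx >= len(z) - 1:
        return float(z[idx])
    y0, y1, y2 = z[idx - 1], z[idx], z[idx + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom <= 0:
        return float(z[idx])
    delta = 0.5 * (y0 - y2) / denom
    if abs(delta) > 1.0:
        return float(z[idx])
    return float(y1 - 0.25 * (y0 - y2) * delta)


def _find_minima(z: np.ndarray, fs: float, f_stride: float) -> np.ndarray:
    distance = max(1, int(round(0.3 / f_stride * fs)))
    idx, props = signal.find_peaks(-z, distance=distance, prominence=0.0)
    if len(idx) < 2:
        raise SegmentationError("fewer than two displacement minima found")
    prom = props["prominences"]
    keep = prom >= 0.2 * np.median(prom)
    return idx[keep]


def segment_strides(trace: MarkerTrace) -> StrideSegmentation:
    """Segment a trace into strides and locate the two stance minima of each.

    Raises ``InsufficientDataError`` with fewer than 5 complete strides and
    ``SegmentationError`` when no dominant trot periodicity exists.
    """
    trace.validate()
    fs = trace.sampling_rate
    f_stride = _dominant_stride_frequency(np.asarray(trace.pelvis_z, float), fs)
    if trace.duration * f_stride < 5.0:
        raise InsufficientDataError(
            f"trace holds {trace.duration * f_stride:.1f} strides; >= 5 required"
        )

    cutoff = 4.0 * f_stride
    pelvis_f = _lowpass(np.asarray(trace.pelvis_z, float), fs, cutoff)
    head_f = _lowpass(np.asarray(trace.head_z, float), fs, cutoff)

    pel_min = _find_minima(pelvis_f, fs, f_stride)
    # drop edge minima whose half-stride search window leaves the trace
    half_win = int(round(0.25 / f_stride * fs))
    pel_min = pel_min[(pel_min >= half_win) & (pel_min < len(pelvis_f) - half_win)]
    n_strides = len(pel_min) // 2
    if n_strides < 5:
        raise InsufficientDataError(
            f"only {n_strides} complete strides segmented; >= 5 required"
        )
    pel_min = pel_min[: 2 * n_strides]

    # alternation check: successive minima should be roughly half a stride apart
    gaps = np.diff(pel_min) / fs
    if np.any(gaps > 0.85 / f_stride) or np.any(gaps < 0.15 / f_stride):
        raise SegmentationError("minima alternation broken (irregular spacing)")

    # head minimum inside a half-stride window around each pelvis minimum
    head_idx = np.empty_like(pel_min)
    for j, i in enumerate(pel_min):
        w0, w1 = i - half_win, i + half_win + 1
        head_idx[j] = w0 + int(np.argmin(head_f[w0:w1]))

    pel_vals = np.array([_refine_minimum(pelvis_f, i) for i in pel_min])
    head_vals = np.array([_refine_minimum(head_f, i) for i in head_idx])

    boundaries = np.concatenate([[max(pel_min[0] - half_win, 0)],
                                 (pel_min[1::2][:-1] + pel_min[2::2]) // 2,
                                 [min(pel_min[-1] + half_win, len(pelvis_f) - 1)]])
    return StrideSegmentation(
        boundaries=boundaries,
        head_minima=head_idx.reshape(n_strides, 2),
        pelvis_minima=pel_min.reshape(n_strides, 2),
        head_values=head_vals.reshape(n_strides, 2),
        pelvis_values=pel_vals.reshape(n_strides, 2),
        stride_frequency=f_stride,
    )


# ------------------------------------------------------------------ metrics

def compute_asymmetry(trace: MarkerTrace, seg: StrideSegmentation) -> AsymmetryResult:
    """Trial-mean HDmin / PDmin from a stride segmentation.

    Per stride, the metric is the side-1 minus side-2 stance minimum; trial
    means are converted to positive (right-side) magnitudes once.
    """
    n_strides = seg.pelvis_values.shape[0]
    if n_strides < 5:
        raise InsufficientDataError("need >= 5 strides for a trial mean")
    hd = float(np.mean(seg.head_values[:, 0] - seg.head_values[:, 1]))
    pd_ = float(np.mean(seg.pelvis_values[:, 0] - seg.pelvis_values[:, 1]))
    return AsymmetryResult(
        hdmin=abs(hd),
        pdmin=abs(pd_),
        n_strides=n_strides,
        hdmin_signed=hd,
        pdmin_signed=pd_,
    )


def compute_tas(current: AsymmetryResult, baseline: AsymmetryResult) -> float:
    """Total Asymmetry Score: |dHDmin|/2 + |dPDmin| versus baseline, mm."""
    if current.side_convention != baseline.side_convention:
        raise ValidationError("TAS requires both results in the same sign convention")
    return abs(current.hdmin - baseline.hdmin) / 2.0 + abs(current.pdmin - baseline.pdmin)


def analyze_trial(trace: MarkerTrace) -> AsymmetryResult:
    """Segment and compute asymmetry in one call."""
    return compute_asymmetry(trace, segment_strides(trace))


def combine_trials(results: Sequence[AsymmetryResult]) -> AsymmetryResult:
    """Average trial means when an occasion has more than one trot trial."""
    if not results:
        raise InsufficientDataError("no trials to combine")
    return AsymmetryResult(
        hdmin=float(np.mean([r.hdmin for r in results])),
        pdmin=float(np.mean([r.pdmin for r in results])),
        n_strides=int(sum(r.n_strides for r in results)),
        hdmin_signed=float(np.mean([r.hdmin_signed for r in results])),
        pdmin_signed=float(np.mean([r.pdmin_signed for r in results])),
    )
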