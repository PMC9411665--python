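"""Synthetic LPS-synovitis study generator.

Emulates the data structure of an induced transient-arthritis experiment:
each horse gets a baseline gait analysis, an asymmetry pulse that rises after
induction, peaks at a horse-specific height (population mean 27 mm, SD 26 mm
Total Asymmetry Score) and decays back below 10% of the peak within 52 h,
serial gait-analysis occasions, and paired before/after pain assessments by
three simultaneous observers (two fixed, one rotating) on four scales with
strong floor effects.

Waveform model for a single trot trial, with stride phase theta = 2*pi*f*t:

    z(t) = A * sin(2*theta) + (d/2) * cos(theta - 3*pi/4) + noise

The fast term gives the two stance-phase minima per stride; the slow term has
zero slope exactly at those minima, so alternate minima differ by exactly
``d`` (the injected HDmin/PDmin) without shifting their location.

All randomness flows from a single root seed through named deterministic
substreams, so identical configurations reproduce byte-identical studies.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import StudyConfig, TrialSpec
from .exceptions import ConfigurationError, EquipainError
from .gait import MarkerTrace, write_trace_tsv
from .scales import PainAssessment, ScaleDefinition, builtin_scales

__all__ = [
    "TasTrajectory",
    "SyntheticStudy",
    "generate_trial_trace",
    "generate_tas_trajectory",
    "generate_pain_assessments",
    "generate_study",
]

# substream purpose codes, fixed for reproducibility
_TRAJ, _PAIN, _TRACE, _DESIGN = 0, 1, 2, 3


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic substream derived from a root seed and integer key path."""
    return np.random.default_rng([int(seed)] + [int(k) for k in key])


# ---------------------------------------------------------------- waveform

def generate_trial_trace(spec: TrialSpec, seed: int,
                         horse_id: str = "", occasion_id: str = "") -> MarkerTrace:
    """Generate one trot trial's vertical head/pelvis traces.

    By construction the difference between alternate minima of each filtered
    series equals the requested asymmetry (exactly, at zero noise).
    """
    spec.validate()
    rng = _rng(seed, _TRACE)
    n = int(round(spec.duration * spec.sampling_rate)) + 1
    t = np.arange(n) / spec.sampling_rate
    phase0 = rng.uniform(0.0, 2.0 * np.pi)
    theta = 2.0 * np.pi * spec.stride_frequency * t + phase0
    head = (spec.head_amplitude * np.sin(2.0 * theta)
            + 0.5 * spec.head_asym * np.cos(theta - 0.75 * np.pi))
    pelvis = (spec.pelvis_amplitude * np.sin(2.0 * theta)
              + 0.5 * spec.pelvis_asym * np.cos(theta - 0.75 * np.pi))
    if spec.noise_sd > 0:
        head = head + rng.normal(0.0, spec.noise_sd, size=n)
        pelvis = pelvis + rng.normal(0.0, spec.noise_sd, size=n)
    return MarkerTrace(time=t, head_z=head, pelvis_z=pelvis,
                       sampling_rate=spec.sampling_rate,
                       horse_id=horse_id, occasion_id=occasion_id)


# -------------------------------------------------------------- trajectory

@dataclass
class TasTrajectory:
    """A horse's true asymmetry-change pulse plus its sampled occasions.

    The pulse is ``P * (t/tau) * exp(1 - t/tau)`` for t > 0 (0 before
    induction): zero at induction, maximum ``P`` at ``t = tau``, decaying
    smoothly afterwards.
    """

    horse_id: str
    peak: float  # P, mm
    peak_time: float  # tau, h
    occasion_times: np.ndarray  # h, baseline first (<= 0), then sorted post times

    def tas_at(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        pos = t > 0
        x = t[pos] / self.peak_time
        out[pos] = self.peak * x * np.exp(1.0 - x)
        return out if out.ndim else float(out)

    @property
    def points(self) -> List[Tuple[float, float]]:
        """(clock_time h, true TAS mm) at each occasion."""
        tas = self.tas_at(self.occasion_times)
        return [(float(t), float(v)) for t, v in zip(self.occasion_times, tas)]


def _draw_peak(cfg: StudyConfig, rng: np.random.Generator) -> float:
    """Log-normal peak TAS with the configured population mean/SD, capped."""
    cv2 = (cfg.peak_tas_sd / cfg.peak_tas_mean) ** 2
    sigma2 = np.log1p(cv2)
    mu = np.log(cfg.peak_tas_mean) - 0.5 * sigma2
    p = float(rng.lognormal(mu, np.sqrt(sigma2)))
    return min(p, cfg.peak_tas_max)


def generate_tas_trajectory(cfg: StudyConfig, horse_id: str, seed: int) -> TasTrajectory:
    """Draw one horse's asymmetry pulse and gait-analysis occasion times."""
    cfg.validate()
    rng = _rng(seed, _TRAJ)
    peak = _draw_peak(cfg, rng)
    tau_hi = cfg.resolution_horizon / 4.89  # keeps pulse < 10% of peak at horizon
    tau = float(np.clip(rng.normal(cfg.peak_time_mean, cfg.peak_time_sd), 3.0, tau_hi))
    n_occ = max(cfg.min_post_occasions + 1,
                int(round(rng.normal(cfg.occasions_per_horse_mean,
                                     cfg.occasions_per_horse_sd))))
    n_post = n_occ - 1
    # post-induction times: draws denser during early pain progression
    # (u^2 mapping), sparser during regression, with >= 1 h separation;
    # occasion spacing is a free design choice
    span = cfg.resolution_horizon - cfg.first_post_time
    for _ in range(200):
        u = rng.uniform(0.0, 1.0, n_post)
        post = np.sort(cfg.first_post_time + span * u ** 2)
        if n_post < 2 or np.min(np.diff(post)) >= 1.0:
            break
    times = np.concatenate([[cfg.baseline_time], np.round(post, 2)])
    return TasTrajectory(horse_id=horse_id, peak=peak, peak_time=tau,
                         occasion_times=times)


# -------------------------------------------------------------- assessments

def _latent_link(tas: np.ndarray, half_saturation: float) -> np.ndarray:
    """Monotone saturating TAS -> latent pain fraction, g(0)=0, g(inf)=1."""
    tas = np.asarray(tas, dtype=float)
    return tas / (tas + half_saturation)


def generate_pain_assessments(
    cfg: StudyConfig,
    trajectory: TasTrajectory,
    scales: Optional[Sequence[ScaleDefinition]] = None,
    seed: int = 0,
) -> List[PainAssessment]:
    """Generate before/after multi-observer pain scores along a trajectory.

    Each kept (occasion, timing) slot is one assessment event: three
    observers (1, 2 and a rotating third) score all four scales
    simultaneously.  Slots are subsampled so the per-horse assessment count
    matches the configured mean/SD.  Scores follow
    ``clip(round(scale_max * (gain*g(TAS) + bias + before_effect + noise)), 0, max)``
    with per-observer zero inflation.
    """
    cfg.validate()
    if scales is None:
        scales = builtin_scales()
    if len(trajectory.occasion_times) == 0:
        raise ConfigurationError("trajectory has no occasions")
    rng = _rng(seed, _PAIN)

    times = np.asarray(trajectory.occasion_times, float)
    n_occ = len(times)
    slots = [(i, timing) for i in range(n_occ) for timing in ("before_gait", "after_gait")]
    target = int(round(rng.normal(cfg.assessments_per_horse_mean,
                                  cfg.assessments_per_horse_sd)))
    target = int(np.clip(target, min(n_occ, len(slots)), len(slots)))
    keep_idx = np.sort(rng.choice(len(slots), size=target, replace=False))

    third_ids = sorted(cfg.third_observer_weights)
    if third_ids:
        weights = np.array([cfg.third_observer_weights[k] for k in third_ids], float)
        weights = weights / weights.sum()
        # the rotating third observer is fixed per occasion (one person on site)
        third_per_occ = [str(rng.choice(third_ids, p=weights)) for _ in range(n_occ)]
    else:
        third_per_occ = []

    out: List[PainAssessment] = []
    for s in keep_idx:
        occ_i, timing = slots[s]
        t = times[occ_i]
        tas = float(trajectory.tas_at(np.array([t]))[0])
        g = float(_latent_link(np.array([tas]), cfg.link_half_saturation_mm)[0])
        phase = "pre_induction" if t <= 0 else "post_induction"
        fixed = [o for o in ("1", "2") if o in cfg.observer_params]
        observers = list(dict.fromkeys(fixed + [third_per_occ[occ_i]])) \
            if third_per_occ else fixed
        for obs_id in observers:
            p = cfg.observer_params[obs_id]
            for scale in scales:
                latent = p.gain * g + p.bias + rng.normal(0.0, p.noise_sd)
                if timing == "before_gait":
                    latent += cfg.before_effect
                if rng.uniform() < p.zero_inflation_prob:
                    total = 0
                else:
                    total = int(np.clip(round(scale.total_max * latent), 0, scale.total_max))
                out.append(PainAssessment(
                    horse_id=trajectory.horse_id,
                    occasion_id=f"occ{occ_i:02d}",
                    observer_id=obs_id,
                    scale=scale.name,
                    total_score=total,
                    timing=timing,
                    phase=phase,
                ))
    return out


# -------------------------------------------------------------------- study

@dataclass
class SyntheticStudy:
    """A complete generated study: occasion table, assessments, trace files."""

    occasions: pd.DataFrame  # horse, occasion, clock_time_h, true_tas_mm, trace_file
    assessments: pd.DataFrame  # long format, one row per observer x scale score
    trajectories: Dict[str, TasTrajectory]
    trace_dir: Optional[Path] = None


def _occasion_trial_spec(cfg: StudyConfig, tas: float, base_hd: float,
                         base_pd: float, stride_frequency: float) -> TrialSpec:
    f = cfg.pelvis_tas_fraction
    return TrialSpec(
        stride_frequency=stride_frequency,
        duration=cfg.trial.duration,
        head_amplitude=cfg.trial.head_amplitude,
        pelvis_amplitude=cfg.trial.pelvis_amplitude,
        head_asym=base_hd + 2.0 * (1.0 - f) * tas,
        pelvis_asym=base_pd + f * tas,
        noise_sd=cfg.trial.noise_sd,
        sampling_rate=cfg.trial.sampling_rate,
    )


def generate_study(cfg: StudyConfig, out_dir: Optional[str | Path] = None) -> SyntheticStudy:
    """Generate a full study; optionally write trace TSVs and tables to disk.

    Injected per-occasion asymmetries reproduce the trajectory TAS exactly:
    dPDmin = f*TAS and dHDmin = 2*(1-f)*TAS on top of the horse's baseline,
    so |dHDmin|/2 + |dPDmin| = TAS.
    """
    cfg.validate()
    scales = builtin_scales()
    trace_dir: Optional[Path] = None
    if out_dir is not None:
        trace_dir = Path(out_dir)
        try:
            trace_dir.mkdir(parents=True, exist_ok=True)
        except OSError as exc:
            raise EquipainError(f"cannot create output dir {trace_dir}: {exc}") from exc

    occ_rows = []
    assess_rows = []
    trajectories: Dict[str, TasTrajectory] = {}
    for h in range(cfg.n_horses):
        horse_id = f"H{h + 1:02d}"
        traj = generate_tas_trajectory(cfg, horse_id, seed=_seed_for(cfg.seed, h, _TRAJ))
        trajectories[horse_id] = traj
        design_rng = _rng(cfg.seed, h, _DESIGN)
        base_hd = abs(design_rng.normal(cfg.baseline_hdmin_mean, cfg.baseline_asym_sd))
        base_pd = abs(design_rng.normal(cfg.baseline_pdmin_mean, cfg.baseline_asym_sd))
        stride_f = design_rng.uniform(1.25, 1.55)

        for i, (t, tas) in enumerate(traj.points):
            occ_id = f"occ{i:02d}"
            spec = _occasion_trial_spec(cfg, tas, base_hd, base_pd, stride_f)
            trial_id = "t1"
            fname = f"{horse_id}_{occ_id}_{trial_id}.tsv"
            if trace_dir is not None:
                trace = generate_trial_trace(
                    spec, seed=_seed_for(cfg.seed, h, _TRACE, i),
                    horse_id=horse_id, occasion_id=occ_id)
                try:
                    write_trace_tsv(trace, trace_dir / fname)
                except OSError as exc:
                    raise EquipainError(
                        f"cannot write trace {trace_dir / fname}: {exc}") from exc
            occ_rows.append({
                "horse": horse_id, "occasion": occ_id,
                "clock_time_h": round(float(t), 2),
                "true_tas_mm": float(tas),
                "trace_file": fname,
            })

        for a in generate_pain_assessments(
                cfg, traj, scales, seed=_seed_for(cfg.seed, h, _PAIN)):
            assess_rows.append({
                "horse": a.horse_id, "occasion": a.occasion_id,
                "observer": a.observer_id, "scale": a.scale,
                "timing": a.timing, "phase": a.phase,
                "total": a.total_score,
            })

    occasions = pd.DataFrame(occ_rows)
    assessments = pd.DataFrame(assess_rows)
    if trace_dir is not None:
        occasions.to_csv(trace_dir / "occasions.csv", index=False, float_format="%.6f")
        assessments.to_csv(trace_dir / "assessments.csv", index=False)
    return SyntheticStudy(occasions=occasions, assessments=assessments,
                          trajectories=trajectories, trace_dir=trace_dir)


def _seed_for(root: int, horse: int, purpose: int, extra: int = 0) -> int:
    """Small deterministic per-(horse, purpose) seed below 2**31."""
    ss = np.random.SeedSequence([int(root), int(horse), int(purpose), int(extra)])
    return int(ss.generate_state(1, np.uint32)[0] % (2 ** 31))
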