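"""Study and trial configuration.

``StudyConfig`` collects every knob of the synthetic LPS-synovitis study
emulation: cohort size, the shape and calibration of the induced-asymmetry
pulse, the occasion/assessment sampling design, and per-observer scoring
behaviour.  ``TrialSpec`` describes a single motion-capture trot trial.

Defaults reproduce the study conditions the generator emulates: 8 horses,
a mean (SD) of 6.6 (1.2) gait-analysis occasions and 12.1 (2.4) pain
assessments per horse, a mean (SD) peak Total Asymmetry Score of 27 (26) mm
resolving within 52 h, three simultaneous observers per assessment (two
fixed, one rotating), and strong floor effects on all four pain scales.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Optional

import yaml

from .exceptions import ConfigurationError

__all__ = [
    "ObserverParams",
    "TrialSpec",
    "StudyConfig",
    "load_config",
    "save_config",
]


@dataclass
class ObserverParams:
    """Latent-score behaviour of one pain assessor.

    The generator maps the horse's true asymmetry change (TAS, mm) to a
    latent score fraction ``gain * g(TAS) + bias + noise`` where ``g`` is a
    monotone saturating link; ``zero_inflation_prob`` is the probability the
    observer records 0 regardless (a floor-effect mechanism).
    """

    gain: float = 0.35
    bias: float = 0.01
    noise_sd: float = 0.04
    zero_inflation_prob: float = 0.35

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ConfigurationError("observer noise_sd must be >= 0")
        if not 0.0 <= self.zero_inflation_prob <= 1.0:
            raise ConfigurationError("zero_inflation_prob must be in [0, 1]")


def default_observer_params() -> Dict[str, ObserverParams]:
    """Five observers spanning careful (1) to noisy (5) scoring behaviour."""
    return {
        "1": ObserverParams(gain=0.40, bias=0.02, noise_sd=0.020, zero_inflation_prob=0.10),
        "2": ObserverParams(gain=0.36, bias=0.00, noise_sd=0.025, zero_inflation_prob=0.12),
        "3": ObserverParams(gain=0.30, bias=0.01, noise_sd=0.030, zero_inflation_prob=0.15),
        "4": ObserverParams(gain=0.25, bias=0.03, noise_sd=0.040, zero_inflation_prob=0.20),
        "5": ObserverParams(gain=0.20, bias=0.00, noise_sd=0.050, zero_inflation_prob=0.25),
    }


@dataclass
class TrialSpec:
    """One straight-line trot trial for the trace generator.

    ``head_asym`` / ``pelvis_asym`` are the intended differences (mm) between
    alternate vertical minima, i.e. the HDmin / PDmin the gait metrics should
    recover.  Amplitudes are the half peak-to-peak of the symmetric
    double-frequency oscillation.
    """

    stride_frequency: float = 1.4  # Hz, trot stride rate
    duration: float = 15.0  # s
    head_amplitude: float = 60.0  # mm
    pelvis_amplitude: float = 45.0  # mm
    head_asym: float = 0.0  # mm
    pelvis_asym: float = 0.0  # mm
    noise_sd: float = 1.0  # mm, iid marker noise
    sampling_rate: float = 200.0  # Hz

    def validate(self) -> None:
        if self.head_amplitude <= 0 or self.pelvis_amplitude <= 0:
            raise ConfigurationError("amplitudes must be > 0")
        if self.stride_frequency <= 0:
            raise ConfigurationError("stride_frequency must be > 0")
        if self.sampling_rate < 20.0 * self.stride_frequency:
            raise ConfigurationError(
                "sampling_rate must be at least 20x stride_frequency "
                f"(got {self.sampling_rate} Hz for {self.stride_frequency} Hz strides)"
            )
        if self.duration * self.stride_frequency < 5.0:
            raise ConfigurationError("duration must contain at least 5 complete strides")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


@dataclass
class StudyConfig:
    """Full synthetic-study configuration (see module docstring for defaults)."""

    n_horses: int = 8
    # per-horse baseline asymmetry (mm): means and between-horse SD of the
    # pre-induction HDmin / PDmin magnitudes
    baseline_hdmin_mean: float = 4.0
    baseline_pdmin_mean: float = 3.0
    baseline_asym_sd: float = 2.0
    # induced-asymmetry pulse calibration
    peak_tas_mean: float = 27.0  # mm
    peak_tas_sd: float = 26.0  # mm
    peak_tas_max: float = 110.0  # mm, severity cap (rescue-analgesia analogue)
    peak_time_mean: float = 8.0  # h post-induction
    peak_time_sd: float = 2.0  # h
    resolution_horizon: float = 52.0  # h; asymmetry back near baseline by here
    # sampling design
    occasions_per_horse_mean: float = 6.6
    occasions_per_horse_sd: float = 1.2
    min_post_occasions: int = 4
    assessments_per_horse_mean: float = 12.1
    assessments_per_horse_sd: float = 2.4
    baseline_time: float = -24.0  # h, clock time of the pre-induction occasion
    first_post_time: float = 1.5  # h, earliest post-induction measurement
    # observers
    observer_params: Dict[str, ObserverParams] = field(default_factory=default_observer_params)
    third_observer_weights: Dict[str, float] = field(
        default_factory=lambda: {"3": 0.6, "4": 0.2, "5": 0.2}
    )
    before_effect: float = 0.03  # latent-fraction elevation of pre-gait scores
    # monotone saturating TAS -> latent pain link, g(t) = t / (t + half_saturation)
    link_half_saturation_mm: float = 60.0
    # split of TAS into pelvis and head components:
    # delta_PDmin = f * TAS, delta_HDmin = 2 * (1 - f) * TAS
    pelvis_tas_fraction: float = 0.6
    trial: TrialSpec = field(default_factory=TrialSpec)
    seed: int = 0

    def validate(self) -> None:
        if self.n_horses < 1:
            raise ConfigurationError("n_horses must be >= 1")
        for name in ("baseline_asym_sd", "peak_tas_sd", "peak_time_sd",
                     "occasions_per_horse_sd", "assessments_per_horse_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.peak_tas_mean <= 0:
            raise ConfigurationError("peak_tas_mean must be > 0")
        if self.resolution_horizon <= self.peak_time_mean:
            raise ConfigurationError("resolution_horizon must exceed peak_time_mean")
        if self.baseline_time > 0:
            raise ConfigurationError("baseline_time must be <= 0 (induction at t=0)")
        if not 0.0 < self.pelvis_tas_fraction < 1.0:
            raise ConfigurationError("pelvis_tas_fraction must be in (0, 1)")
        if self.link_half_saturation_mm <= 0:
            raise ConfigurationError("link_half_saturation_mm must be > 0")
        if self.min_post_occasions < 1:
            raise ConfigurationError("min_post_occasions must be >= 1")
        if not self.observer_params:
            raise ConfigurationError("at least one observer must be configured")
        for obs_id, p in self.observer_params.items():
            if not isinstance(p, ObserverParams):
                raise ConfigurationError(f"observer {obs_id}: params must be ObserverParams")
            p.validate()
        for obs_id in self.third_observer_weights:
            if obs_id not in self.observer_params:
                raise ConfigurationError(f"third observer {obs_id!r} has no observer_params")
        self.trial.validate()

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "observer_params" in d:
            d["observer_params"] = {
                str(k): ObserverParams(**v) if isinstance(v, dict) else v
                for k, v in d["observer_params"].items()
            }
        if "trial" in d and isinstance(d["trial"], dict):
            d["trial"] = TrialSpec(**d["trial"])
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg


def load_config(path: str | Path) -> StudyConfig:
    """Read a StudyConfig from a YAML (or JSON, a YAML subset) document."""
    path = Path(path)
    try:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    except OSError as exc:
        raise ConfigurationError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigurationError(f"config {path} must be a single mapping document")
    return StudyConfig.from_dict(doc)


def save_config(cfg: StudyConfig, path: str | Path) -> None:
    cfg.validate()
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
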