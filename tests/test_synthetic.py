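"""Synthetic-study generator: determinism, calibration, structure."""
import numpy as np
import pandas as pd
import pytest

from equipain.config import ObserverParams, StudyConfig, TrialSpec
from equipain.exceptions import ConfigurationError
from equipain.scales import builtin_scales
from equipain.synthetic import (generate_pain_assessments, generate_study,
                                generate_tas_trajectory, generate_trial_trace)


def test_invalid_trial_spec_rejected():
    with pytest.raises(ConfigurationError):
        TrialSpec(sampling_rate=10.0).validate()  # < 20x stride frequency
    with pytest.raises(ConfigurationError):
        TrialSpec(duration=2.0).validate()  # < 5 strides
    with pytest.raises(ConfigurationError):
        StudyConfig(resolution_horizon=5.0).validate()


def test_trace_determinism():
    spec = TrialSpec(head_asym=5.0, noise_sd=1.0)
    a = generate_trial_trace(spec, seed=42)
    b = generate_trial_trace(spec, seed=42)
    np.testing.assert_array_equal(a.head_z, b.head_z)
    np.testing.assert_array_equal(a.pelvis_z, b.pelvis_z)


def test_symmetric_noise_free_minima_equal():
    """With zero asymmetry and zero noise, alternate sampled minima coincide
    (up to the sampling discretization of the minimum value)."""
    spec = TrialSpec(head_asym=0.0, pelvis_asym=0.0, noise_sd=0.0,
                     sampling_rate=2000.0)
    trace = generate_trial_trace(spec, seed=1)
    z = trace.head_z
    mins = z[[i for i in range(1, len(z) - 1)
              if z[i] < z[i - 1] and z[i] < z[i + 1]]]
    assert abs(mins[0::2].mean() - mins[1::2].mean()) < 2e-3
    assert z.min() == pytest.approx(-spec.head_amplitude, abs=1e-3)


def test_alternate_minima_differ_by_requested_asymmetry():
    """Numerically locate minima of the constructed waveform and difference."""
    spec = TrialSpec(pelvis_asym=10.0, noise_sd=0.0, sampling_rate=2000.0)
    trace = generate_trial_trace(spec, seed=1)
    z = trace.pelvis_z
    mins = [i for i in range(1, len(z) - 1) if z[i] < z[i - 1] and z[i] < z[i + 1]]
    vals = z[mins]
    diffs = np.abs(vals[0::2].mean() - vals[1::2].mean())
    assert diffs == pytest.approx(10.0, abs=0.01)


def test_trajectory_pulse_shape():
    cfg = StudyConfig()
    traj = generate_tas_trajectory(cfg, "H01", seed=5)
    assert traj.tas_at(np.array([0.0]))[0] == 0.0
    assert traj.tas_at(np.array([traj.peak_time]))[0] == pytest.approx(traj.peak)
    assert traj.tas_at(np.array([cfg.resolution_horizon]))[0] < 0.1 * traj.peak
    # baseline occasion present at t <= 0, post occasions sorted
    assert traj.occasion_times[0] <= 0
    assert np.all(np.diff(traj.occasion_times) > 0)
    assert len(traj.occasion_times) >= cfg.min_post_occasions + 1


def test_peak_calibration_large_sample():
    cfg = StudyConfig()
    peaks = [generate_tas_trajectory(cfg, f"H{i}", seed=i).peak for i in range(1000)]
    assert np.mean(peaks) == pytest.approx(cfg.peak_tas_mean, rel=0.10)


def test_degenerate_assessments_all_zero():
    cfg = StudyConfig(
        observer_params={"1": ObserverParams(gain=0.0, bias=0.0, noise_sd=0.0,
                                             zero_inflation_prob=1.0)},
        third_observer_weights={}, before_effect=0.0)
    # only observer 1 configured; make it the rotating third too
    cfg.third_observer_weights = {"1": 1.0}
    traj = generate_tas_trajectory(cfg, "H01", seed=1)
    out = generate_pain_assessments(cfg, traj, seed=1)
    assert len(out) > 0
    assert all(a.total_score == 0 for a in out)


def test_scores_monotone_in_tas_without_noise():
    cfg = StudyConfig(
        observer_params={"1": ObserverParams(gain=0.5, bias=0.0, noise_sd=0.0,
                                             zero_inflation_prob=0.0)},
        third_observer_weights={"1": 1.0}, before_effect=0.0)
    traj = generate_tas_trajectory(cfg, "H01", seed=2)
    out = generate_pain_assessments(cfg, traj, seed=2)
    by_tas = sorted((float(traj.tas_at(np.array([traj.occasion_times[
        int(a.occasion_id[3:])]]))[0]), a.total_score)
        for a in out if a.scale == "CPS" and a.timing == "after_gait")
    tot = [s for _, s in by_tas]
    assert all(a <= b for a, b in zip(tot, tot[1:]))


def test_assessment_count_calibration():
    cfg = StudyConfig(seed=4)
    study = generate_study(cfg)
    events = study.assessments.drop_duplicates(
        subset=["horse", "occasion", "timing"])
    per_horse = len(events) / cfg.n_horses
    band = 2 * cfg.assessments_per_horse_sd
    assert abs(per_horse - cfg.assessments_per_horse_mean) <= band


def test_study_design_structure():
    cfg = StudyConfig(seed=7)
    study = generate_study(cfg)
    assert study.occasions["horse"].nunique() == 8
    baselines = study.occasions[study.occasions["clock_time_h"] <= 0]
    assert (baselines.groupby("horse").size() == 1).all()
    # baseline TAS is zero by construction
    assert (baselines["true_tas_mm"] == 0).all()
    # three observers per assessment event
    obs_per_event = study.assessments.groupby(
        ["horse", "occasion", "timing"])["observer"].nunique()
    assert (obs_per_event == 3).all()
    # all four scales present
    assert set(study.assessments["scale"]) == {s.name for s in builtin_scales()}


def test_study_determinism_byte_identical(tmp_path):
    cfg = StudyConfig(n_horses=2, seed=5)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    generate_study(cfg, out_dir=d1)
    generate_study(cfg, out_dir=d2)
    files1 = sorted(p.name for p in d1.iterdir())
    assert files1 == sorted(p.name for p in d2.iterdir())
    for name in files1:
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes()


def test_floor_effect_default_parameters():
    """Majority of generated totals sit at <= 10% of each scale's maximum."""
    study = generate_study(StudyConfig(seed=2))
    sm = {s.name: s.total_max for s in builtin_scales()}
    frac = np.mean([
        t <= 0.1 * sm[s]
        for s, t in zip(study.assessments["scale"], study.assessments["total"])])
    assert frac >= 0.5
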