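"""Stride segmentation and asymmetry-metric recovery."""
import numpy as np
import pytest

from equipain.config import TrialSpec
from equipain.exceptions import (ConfigurationError, InsufficientDataError,
                                 SegmentationError)
from equipain.gait import (AsymmetryResult, MarkerTrace, analyze_trial,
                           compute_asymmetry, compute_tas, read_trace_tsv,
                           segment_strides, write_trace_tsv)
from equipain.synthetic import generate_trial_trace


def make_trace(head_asym=0.0, pelvis_asym=0.0, noise_sd=0.0, seed=1, **kw):
    spec = TrialSpec(head_asym=head_asym, pelvis_asym=pelvis_asym,
                     noise_sd=noise_sd, **kw)
    return generate_trial_trace(spec, seed=seed)


def test_stride_count_matches_frequency_times_duration():
    # 1.4 Hz for 10 s = 14 stride cycles; edge-trimming may cost one
    trace = make_trace(stride_frequency=1.4, duration=10.0)
    seg = segment_strides(trace)
    assert seg.pelvis_minima.shape[1] == 2
    assert 13 <= seg.pelvis_minima.shape[0] <= 14
    assert seg.stride_frequency == pytest.approx(1.4, abs=0.05)


def test_noise_preserves_stride_count():
    clean = segment_strides(make_trace(stride_frequency=1.4, duration=10.0, seed=7))
    noisy = segment_strides(make_trace(stride_frequency=1.4, duration=10.0,
                                       noise_sd=1.0, seed=7))
    assert noisy.pelvis_minima.shape[0] == clean.pelvis_minima.shape[0]


def test_short_trace_rejected():
    with pytest.raises((InsufficientDataError, ConfigurationError)):
        trace = make_trace(duration=10.0)
        # truncate to ~2 strides
        n = int(2.2 / 1.4 * 200)
        short = MarkerTrace(time=trace.time[:n], head_z=trace.head_z[:n],
                            pelvis_z=trace.pelvis_z[:n],
                            sampling_rate=trace.sampling_rate)
        segment_strides(short)


def test_aperiodic_signal_rejected():
    rng = np.random.default_rng(0)
    t = np.arange(0, 10, 1 / 200)
    z = rng.normal(0, 5, len(t))
    trace = MarkerTrace(time=t, head_z=z, pelvis_z=z, sampling_rate=200.0)
    with pytest.raises(SegmentationError):
        segment_strides(trace)


def test_symmetric_trace_has_zero_asymmetry():
    res = analyze_trial(make_trace(0.0, 0.0))
    assert res.hdmin == pytest.approx(0.0, abs=0.01)
    assert res.pdmin == pytest.approx(0.0, abs=0.01)


@pytest.mark.parametrize("head_asym,pelvis_asym", [(0, 5), (5, 0), (10, 10), (20, 5)])
def test_injected_asymmetry_recovered_noise_free(head_asym, pelvis_asym):
    res = analyze_trial(make_trace(head_asym, pelvis_asym))
    assert res.hdmin == pytest.approx(head_asym, abs=0.1)
    assert res.pdmin == pytest.approx(pelvis_asym, abs=0.1)


@pytest.mark.parametrize("asym", [0.0, 5.0, 10.0, 20.0])
def test_recovery_grid_with_noise(asym):
    res = analyze_trial(make_trace(asym, asym, noise_sd=1.0, seed=3))
    assert res.hdmin == pytest.approx(asym, abs=1.0)
    assert res.pdmin == pytest.approx(asym, abs=1.0)


def test_mirrored_trace_same_magnitude():
    """Side-1/side-2 swap (negated injected asymmetry) flips the sign of the
    trial mean but leaves the converted magnitude unchanged."""
    res = analyze_trial(make_trace(10.0, 6.0, seed=5))
    res_m = analyze_trial(make_trace(-10.0, -6.0, seed=5))
    assert np.sign(res_m.hdmin_signed) == -np.sign(res.hdmin_signed)
    assert res_m.hdmin == pytest.approx(res.hdmin, abs=0.05)
    assert res_m.pdmin == pytest.approx(res.pdmin, abs=0.05)


def test_amplitude_invariance():
    lo = analyze_trial(make_trace(8.0, 4.0, seed=2, head_amplitude=40.0,
                                  pelvis_amplitude=30.0))
    hi = analyze_trial(make_trace(8.0, 4.0, seed=2, head_amplitude=80.0,
                                  pelvis_amplitude=60.0))
    assert hi.hdmin == pytest.approx(lo.hdmin, abs=0.05)
    assert hi.pdmin == pytest.approx(lo.pdmin, abs=0.05)


def test_downsampling_invariance():
    trace = make_trace(10.0, 5.0, seed=4)
    res_200 = analyze_trial(trace)
    half = MarkerTrace(time=trace.time[::2], head_z=trace.head_z[::2],
                       pelvis_z=trace.pelvis_z[::2], sampling_rate=100.0)
    res_100 = analyze_trial(half)
    assert res_100.hdmin == pytest.approx(res_200.hdmin, abs=0.5)
    assert res_100.pdmin == pytest.approx(res_200.pdmin, abs=0.5)


def test_tas_formula():
    base = AsymmetryResult(hdmin=4.0, pdmin=2.0, n_strides=10)
    cur = AsymmetryResult(hdmin=10.0, pdmin=8.0, n_strides=10)
    assert compute_tas(cur, base) == pytest.approx(9.0)
    assert compute_tas(base, base) == 0.0
    only_head = AsymmetryResult(hdmin=24.0, pdmin=2.0, n_strides=10)
    assert compute_tas(only_head, base) == pytest.approx(10.0)


def test_trace_roundtrip_io(tmp_path):
    trace = make_trace(3.0, 2.0, noise_sd=0.5, seed=9)
    write_trace_tsv(trace, tmp_path / "t.tsv")
    back = read_trace_tsv(tmp_path / "t.tsv")
    np.testing.assert_allclose(back.head_z, trace.head_z, atol=1e-6)
    np.testing.assert_allclose(back.pelvis_z, trace.pelvis_z, atol=1e-6)
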