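import numpy as np
import pandas as pd
import pytest

from tiltsim.core import TiltProtocol
from tiltsim.params import SubjectConfig
from tiltsim.protocol_analysis import (BeatMetrics, SimulationResult,
                                       beat_stats, detect_beats,
                                       format_report, load_reference,
                                       make_fixture_waveforms,
                                       percent_change, steady_state_metrics,
                                       validation_report, volume_shift)


def synthetic_result(period=1.0, duration=40.0, fs=200.0, mean=90.0,
                     amplitude=20.0):
    t, x = make_fixture_waveforms(dict(period=period, mean=mean,
                                       amplitude=amplitude,
                                       duration=duration, fs=fs))
    beats = np.arange(0.0, duration + 1e-9, period)
    channels = {"p_ao": x, "flat": np.full_like(x, 7.0),
                "q_av": np.zeros_like(x)}
    prot = TiltProtocol(segments=((0.0, duration),))
    return SimulationResult(time=t, channels=channels, beats=beats,
                            angle=np.zeros_like(t), config=SubjectConfig(),
                            protocol=prot)


class TestBeatStats:
    def test_constant_trace(self):
        res = synthetic_result()
        idx = detect_beats(res)
        m, p = beat_stats(res.channels["flat"], res.time, idx)
        assert np.allclose(m, 7.0)
        assert np.allclose(p, 0.0)

    def test_sine_over_whole_periods(self):
        res = synthetic_result(mean=90.0, amplitude=20.0)
        idx = detect_beats(res)
        m, p = beat_stats(res.channels["p_ao"], res.time, idx)
        assert np.allclose(m, 90.0, atol=1e-6)
        # sampled extrema undershoot the analytic 2A by at most O((dt/T)^2)
        assert np.allclose(p, 40.0, atol=0.02)

    def test_two_harmonic_pulse_matches_dense_grid(self):
        spec = dict(period=0.8, mean=80.0, amplitude=15.0,
                    harmonics=[(2, 6.0, 1.1)], duration=8.0, fs=500.0)
        t, x = make_fixture_waveforms(spec)
        tf, xf = make_fixture_waveforms({**spec, "fs": 100000.0,
                                         "duration": 0.8})
        pulse_dense = xf.max() - xf.min()
        beats = np.arange(0.0, 8.0 + 1e-9, 0.8)
        idx = np.searchsorted(t, beats)
        _, p = beat_stats(x, t, idx)
        assert np.allclose(p, pulse_dense, atol=0.02)

    def test_trapezoid_mean_matches_fine_quadrature(self):
        res = synthetic_result(fs=200.0)
        res_fine = synthetic_result(fs=5000.0)
        m, _ = beat_stats(res.channels["p_ao"], res.time, detect_beats(res))
        mf, _ = beat_stats(res_fine.channels["p_ao"], res_fine.time,
                           detect_beats(res_fine))
        assert np.allclose(m, mf, atol=1e-6 * 90.0)

    def test_empty_beat_rejected(self):
        res = synthetic_result()
        with pytest.raises(ValueError):
            beat_stats(res.channels["p_ao"], res.time, np.array([5, 5]))

    def test_zero_amplitude_gives_zero_pulse(self):
        res = synthetic_result(amplitude=0.0)
        _, p = beat_stats(res.channels["p_ao"], res.time, detect_beats(res))
        assert np.allclose(p, 0.0)


class TestBeatDetection:
    def test_counts_beats_from_simulator_clock(self):
        # 60 bpm over a 10 s span -> 10 complete beats (11 boundaries)
        res = synthetic_result(period=1.0, duration=10.2)
        idx = detect_beats(res)
        assert len(idx) - 1 == 10
        assert np.allclose(np.diff(res.time[idx]), 1.0, atol=1e-2)


class TestPercentChange:
    def test_identity(self):
        assert percent_change(10.0, 10.0) == 0.0

    def test_reported_transitions(self):
        assert percent_change(15.9, 9.0) == pytest.approx(-43.4, abs=0.1)
        assert percent_change(49.6, 65.1) == pytest.approx(31.25, abs=0.05)

    def test_negative_baseline_keeps_sign_convention(self):
        assert percent_change(-10.0, -5.0) == pytest.approx(-50.0)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 1.0)


class TestSteadyMetrics:
    def test_constant_trace_reproduced(self):
        res = synthetic_result()
        m = steady_state_metrics(res, (10.0, 39.0))
        assert m.mean["flat"] == pytest.approx(7.0)
        assert m.pulse["flat"] == pytest.approx(0.0, abs=1e-12)
        assert m.hr == pytest.approx(60.0)
        assert m.co == pytest.approx(m.hr * m.sv / 1000.0)

    def test_short_window_rejected(self):
        res = synthetic_result()
        with pytest.raises(ValueError):
            steady_state_metrics(res, (0.0, 3.0))

    def test_pulse_nonnegativity_enforced(self):
        with pytest.raises(ValueError):
            BeatMetrics(mean={}, pulse={"x": -1.0}, hr=60.0, sv=70.0, co=4.2)


def test_simulation_result_validation():
    res = synthetic_result()
    with pytest.raises(ValueError):
        SimulationResult(time=res.time[::-1], channels=res.channels,
                         beats=res.beats, angle=res.angle,
                         config=res.config, protocol=res.protocol)
    with pytest.raises(ValueError):
        SimulationResult(time=res.time, channels={"x": res.time[:-5]},
                         beats=res.beats, angle=res.angle,
                         config=res.config, protocol=res.protocol)


def test_save_load_round_trip(tmp_path):
    res = synthetic_result(duration=6.0)
    res.save(tmp_path / "run")
    back = SimulationResult.load(str(tmp_path / "run"))
    assert np.allclose(back.time, res.time)
    assert np.allclose(back.channels["p_ao"], res.channels["p_ao"],
                       rtol=1e-5)
    assert back.protocol.segments == res.protocol.segments


def test_validation_report_zero_deviation_for_identical_values():
    ref = pd.DataFrame([
        dict(name="aortic MAP", channel="p_ao", kind="mean", units="mmHg",
             pre=92.8, post=86.1, location="x"),
    ])
    pre = BeatMetrics(mean={"p_ao": 92.8}, pulse={"p_ao": 40.0},
                      hr=72.0, sv=72.0, co=5.2)
    post = BeatMetrics(mean={"p_ao": 86.1}, pulse={"p_ao": 45.0},
                       hr=68.0, sv=94.0, co=6.4)
    df = validation_report(pre, post, reference=ref)
    assert df.iloc[0]["dev_pre"] == 0.0
    assert df.iloc[0]["dev_post"] == 0.0
    assert bool(df.iloc[0]["direction_ok"])
    assert "direction of change agrees" in format_report(df)


def test_packaged_reference_table_loads():
    ref = load_reference()
    assert {"name", "channel", "kind", "pre", "post"} <= set(ref.columns)
    assert len(ref) >= 15
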