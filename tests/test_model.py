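import numpy as np
import pytest

from tiltsim.core import TiltProtocol
from tiltsim.model import (CH, build_runtime, initial_state, run_segment)
from tiltsim.params import SubjectConfig


def fixed_angle_knots(angle):
    return (np.array([0.0, 1e9]), np.array([angle, angle]))


@pytest.fixture(scope="module")
def settled_run():
    """120 s at 80 deg head-up from a cold start (shared)."""
    cfg = SubjectConfig()
    rt = build_runtime(cfg)
    rt.y = initial_state(rt, 80.0)
    rt.beats = []
    ts, out = run_segment(rt, fixed_angle_knots(80.0), 120.0)
    return rt, ts, out


def test_total_blood_volume_conserved(settled_run):
    """Closed loop: total volume (all compartments + CSF store) stays
    within 0.1 ml over a minute of beating."""
    _, ts, out = settled_run
    tv = out[:, CH["total_volume"]]
    sl = ts > 60.0
    assert tv[sl].max() - tv[sl].min() < 0.1


def test_reaches_periodic_orbit(settled_run):
    """Beat-to-beat aortic mean drift below 0.01 mmHg/beat after the
    transient (gravity fixed, controls active)."""
    rt, ts, out = settled_run
    beats = np.array(rt.beats)
    beats = beats[(beats > 90.0) & (beats < ts[-1])]
    idx = np.searchsorted(ts, beats)
    pm = [out[idx[i]:idx[i + 1], CH["p_ao"]].mean()
          for i in range(len(idx) - 1)]
    drift = abs(np.polyfit(np.arange(len(pm)), pm, 1)[0])
    assert drift < 0.01


def test_determinism_bitwise(settled_run):
    """Identical configuration twice: bitwise identical trajectories."""
    cfg = SubjectConfig()
    outs = []
    for _ in range(2):
        rt = build_runtime(cfg)
        rt.y = initial_state(rt, 80.0)
        ts, out = run_segment(rt, fixed_angle_knots(80.0), 8.0)
        outs.append(out)
    assert np.array_equal(outs[0], outs[1])


def test_cvp_rises_head_down(settled_run):
    """Direction check: central venous pressure is higher at 6 deg
    head-down than at 80 deg head-up."""
    cfg = SubjectConfig()
    rt = build_runtime(cfg)
    rt.y = initial_state(rt, 80.0)
    ts, out = run_segment(rt, fixed_angle_knots(80.0), 150.0)
    cvp_hut = out[ts > 120, CH["p_ra"]].mean()
    rt2 = build_runtime(cfg)
    rt2.y = initial_state(rt2, -6.0)
    ts2, out2 = run_segment(rt2, fixed_angle_knots(-6.0), 150.0)
    cvp_hdt = out2[ts2 > 120, CH["p_ra"]].mean()
    assert cvp_hdt > cvp_hut + 2.0


def test_open_loop_magnifies_posture_response():
    """Removing the reflexes enlarges the steady MAP difference between
    postures: the controls buffer the tilt."""
    def map_diff(enabled):
        cfg = SubjectConfig()
        cfg.control.enabled = enabled
        maps = {}
        for ang in (80.0, -6.0):
            rt = build_runtime(cfg)
            rt.y = initial_state(rt, ang)
            ts, out = run_segment(rt, fixed_angle_knots(ang), 150.0)
            maps[ang] = out[ts > 120, CH["p_ao"]].mean()
        return abs(maps[-6.0] - maps[80.0])

    assert map_diff(False) > map_diff(True) + 2.0


def test_volume_perturbation_decays():
    """A 10% blood-volume step with controls active produces a MAP
    transient that decays (no growing oscillation over 120 s)."""
    cfg = SubjectConfig()
    cfg.total_blood_volume = 1.1 * cfg.total_blood_volume
    rt = build_runtime(cfg)
    rt.y = initial_state(rt, 80.0)
    ts, out = run_segment(rt, fixed_angle_knots(80.0), 180.0)
    beats = np.array(rt.beats)
    beats = beats[(beats > 30.0) & (beats < ts[-1])]
    idx = np.searchsorted(ts, beats)
    pm = np.array([out[idx[i]:idx[i + 1], CH["p_ao"]].mean()
                   for i in range(len(idx) - 1)])
    early = np.std(pm[:20])
    late = np.std(pm[-20:])
    assert late < early + 0.5
    assert np.all(np.isfinite(out))


def test_carotid_afferent_carries_hydrostatic_column():
    """At matched aortic pressure the sensed carotid pressure is lower
    upright than supine: the afferent includes the heart-to-sinus column."""
    cfg = SubjectConfig()
    diffs = {}
    for ang in (80.0, 0.0):
        rt = build_runtime(cfg)
        rt.y = initial_state(rt, ang)
        ts, out = run_segment(rt, fixed_angle_knots(ang), 60.0)
        sl = ts > 40
        diffs[ang] = (out[sl, CH["p_ao"]] - out[sl, CH["p_cs"]]).mean()
    assert diffs[80.0] > diffs[0.0] + 10.0


def test_tlp_opp_identities_exact(settled_run):
    _, ts, out = settled_run
    assert np.array_equal(out[:, CH["tlp"]],
                          out[:, CH["iop"]] - out[:, CH["icp"]])
    assert np.array_equal(out[:, CH["opp"]],
                          out[:, CH["pa_eye"]] - out[:, CH["iop"]])


def test_all_traces_finite_no_nan(settled_run):
    _, _, out = settled_run
    assert np.all(np.isfinite(out))
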