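"""Protocol orchestration and derived metrics.

Runs the full tilt protocol on the closed-loop model, detects beats from
the simulator's own beat clock, computes beat-averaged (mean) and pulse
(max - min) statistics per site, extracts steady-state windows, tracks
volume shifts, and tabulates the model against the packaged reference
values (beat-averaged operating points of the calibrated subject).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .core import TiltProtocol, tilt_angle_at
from .model import CH, NCH, CHANNELS, build_runtime, initial_state, run_segment
from .params import SubjectConfig


@dataclass
class SimulationResult:
    """Time series (sampled at the configured output rate), beat boundary
    times from the simulator clock, and run metadata."""
    time: np.ndarray
    channels: dict[str, np.ndarray]
    beats: np.ndarray
    angle: np.ndarray
    config: SubjectConfig
    protocol: TiltProtocol
    log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.time)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        for k, v in self.channels.items():
            if len(v) != n:
                raise ValueError(f"channel {k} length mismatch")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.time, "angle": self.angle})
        for k, v in self.channels.items():
            df[k] = v
        return df

    def save(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        self.to_frame().to_csv(os.path.join(outdir, "timeseries.csv"),
                               index=False, float_format="%.6g")
        np.savetxt(os.path.join(outdir, "beats.csv"), self.beats,
                   header="beat_time_s", comments="")
        self.config.to_yaml(os.path.join(outdir, "config.yaml"))
        with open(os.path.join(outdir, "run.json"), "w") as f:
            json.dump({"log": self.log,
                       "protocol": {"segments": list(map(list, self.protocol.segments)),
                                    "ramp_duration": self.protocol.ramp_duration,
                                    "t0": self.protocol.t0}}, f, indent=1)

    @classmethod
    def load(cls, outdir: str) -> "SimulationResult":
        df = pd.read_csv(os.path.join(outdir, "timeseries.csv"))
        beats = np.loadtxt(os.path.join(outdir, "beats.csv"), skiprows=1)
        with open(os.path.join(outdir, "run.json")) as f:
            meta = json.load(f)
        cfg = SubjectConfig.from_yaml(os.path.join(outdir, "config.yaml"))
        prot = TiltProtocol(segments=tuple(map(tuple, meta["protocol"]["segments"])),
                            ramp_duration=meta["protocol"]["ramp_duration"],
                            t0=meta["protocol"]["t0"])
        ch = {k: df[k].to_numpy() for k in df.columns if k not in ("time", "angle")}
        return cls(time=df["time"].to_numpy(), channels=ch, beats=np.atleast_1d(beats),
                   angle=df["angle"].to_numpy(), config=cfg, protocol=prot,
                   log=meta.get("log", {}))


@dataclass
class BeatMetrics:
    """Per-site beat-averaged and pulse values over a steady window, plus
    global per-beat quantities."""
    mean: dict[str, float]
    pulse: dict[str, float]
    hr: float
    sv: float
    co: float          # l/min

    def __post_init__(self) -> None:
        if any(v < -1e-9 for v in self.pulse.values()):
            raise ValueError("pulse values must be non-negative")


def run_protocol(config: SubjectConfig, protocol: TiltProtocol | None = None,
                 settle: float = 240.0, mode: str = "reduced",
                 max_settle_beats: int = 300) -> SimulationResult:
    """Simulate the tilt protocol from a periodic steady state.

    The model first settles at the protocol's starting angle (not
    recorded); settling continues in 30 s blocks until the beat-mean aortic
    pressure drift falls below 0.05 mmHg/beat, erroring out after
    ``max_settle_beats`` beats.  The run itself is deterministic: identical
    configurations give identical outputs.
    """
    protocol = protocol or TiltProtocol()
    if mode == "1d":
        from .coupled1d import run_protocol_1d
        return run_protocol_1d(config, protocol, settle=settle)
    if mode != "reduced":
        raise ValueError(f"unknown mode {mode!r}")
    angle0 = protocol.segments[0][0]
    rt = build_runtime(config)
    rt.y = initial_state(rt, angle0)
    rt.beats = []
    settle_knots = (np.array([0.0, 1e9]), np.array([angle0, angle0]))
    drift = np.inf
    t_settled = 0.0
    while True:
        target = min(settle, 1e9) if t_settled == 0.0 else rt.t + 30.0
        ts, out = run_segment(rt, settle_knots, max(target, rt.t + 30.0))
        beats = np.array(rt.beats)
        bidx = np.searchsorted(ts, beats[(beats > ts[0]) & (beats < ts[-1])])
        if len(bidx) > 12:
            pm = [out[bidx[i]:bidx[i + 1], CH["p_ao"]].mean()
                  for i in range(len(bidx) - 11, len(bidx) - 1)]
            drift = abs(np.polyfit(np.arange(len(pm)), pm, 1)[0])
            t_settled = rt.t
            if drift < 0.05:
                break
        n_beats = len(rt.beats)
        if n_beats > max_settle_beats:
            raise RuntimeError(
                f"no periodic steady state within {max_settle_beats} beats "
                f"(beat-mean aortic drift {drift:.3f} mmHg/beat)")
    t_off = rt.t
    rt.beats = []
    knots_t, knots_a = protocol.knots()
    shifted = (knots_t + t_off, knots_a)
    ts, out = run_segment(rt, shifted, t_off + protocol.duration)
    time = ts - t_off
    channels = {name: out[:, k].copy() for name, k in CH.items()
                if name != "err_flag"}
    beats = np.array(rt.beats) - t_off
    angle = np.asarray(tilt_angle_at(time, protocol))
    cfg_hash = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    log = dict(mode=mode, settle_s=float(t_off), settle_drift=float(drift),
               dt=config.dt, n_samples=len(time), n_beats=len(beats),
               config_sha=cfg_hash)
    return SimulationResult(time=time, channels=channels, beats=beats,
                            angle=angle, config=config, protocol=protocol,
                            log=log)


def detect_beats(result: SimulationResult) -> np.ndarray:
    """Beat boundary indices into the sample grid, taken from the
    simulator's own beat clock (ventricular activation onsets)."""
    b = result.beats
    b = b[(b >= result.time[0]) & (b <= result.time[-1])]
    return np.searchsorted(result.time, b)


def beat_stats(trace: np.ndarray, time: np.ndarray,
               boundaries: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-beat (time-weighted mean, max - min) of a sampled trace."""
    if len(boundaries) < 2:
        raise ValueError("need at least one complete beat")
    means = np.empty(len(boundaries) - 1)
    pulses = np.empty(len(boundaries) - 1)
    for i in range(len(boundaries) - 1):
        a, b = boundaries[i], boundaries[i + 1]
        if b <= a + 1:
            raise ValueError(f"empty beat between samples {a} and {b}")
        seg = trace[a:b + 1]
        tt = time[a:b + 1]
        means[i] = np.trapezoid(seg, tt) / (tt[-1] - tt[0])
        pulses[i] = seg.max() - seg.min()
    return means, pulses


def steady_state_metrics(result: SimulationResult,
                         window: tuple[float, float],
                         n_beats: int = 10,
                         drift_tol: float = 0.05) -> BeatMetrics:
    """Beat metrics averaged over the last ``n_beats`` full beats inside a
    constant-angle window; errors if the beat-mean aortic pressure still
    drifts faster than ``drift_tol`` mmHg/beat there."""
    t0, t1 = window
    idx = detect_beats(result)
    tb = result.time[idx]
    sel = np.where((tb >= t0) & (tb <= t1))[0]
    if len(sel) < n_beats + 1:
        raise ValueError(f"window {window} holds fewer than {n_beats} beats")
    j0 = min(np.searchsorted(result.time, t0), len(result.angle) - 1)
    j1 = max(np.searchsorted(result.time, t1 - 1e-9) - 1, j0)
    a0 = result.angle[j0]
    a1 = result.angle[j1]
    if abs(a0 - a1) > 1e-6:
        raise ValueError("steady-state window must lie within a dwell")
    bsel = idx[sel[-(n_beats + 1):]]
    pm, _ = beat_stats(result.channels["p_ao"], result.time, bsel)
    drift = abs(np.polyfit(np.arange(len(pm)), pm, 1)[0])
    if drift > drift_tol:
        raise ValueError(
            f"beat-mean drift {drift:.3f} mmHg/beat exceeds {drift_tol}; "
            "use a longer dwell before the measurement window")
    mean = {}
    pulse = {}
    for name, tr in result.channels.items():
        m, p = beat_stats(tr, result.time, bsel)
        mean[name] = float(m.mean())
        pulse[name] = float(p.mean())
    per = np.diff(result.time[bsel])
    hr = 60.0 / per.mean()
    sv_each = [np.trapezoid(result.channels["q_av"][bsel[i]:bsel[i + 1] + 1],
                            result.time[bsel[i]:bsel[i + 1] + 1])
               for i in range(len(bsel) - 1)]
    sv = float(np.mean(sv_each))
    return BeatMetrics(mean=mean, pulse=pulse, hr=float(hr), sv=sv,
                       co=float(hr * sv / 1000.0))


def percent_change(pre: float, post: float) -> float:
    """100 (post - pre)/pre, sign-preserving for negative baselines."""
    if pre == 0:
        raise ValueError("percent change undefined for a zero baseline")
    return 100.0 * (post - pre) / pre


def volume_shift(result: SimulationResult,
                 pre_window: tuple[float, float] | None = None) -> dict[str, np.ndarray]:
    """Volume traces re-referenced to their pre-tilt steady beat means:
    eye globe (per eye), cerebral veins, extra-cerebral head veins."""
    if pre_window is None:
        pre_window = result.protocol.window(0)
        pre_window = (pre_window[1] - 60.0, pre_window[1])
    m = steady_state_metrics(result, pre_window)
    return {
        "d_v_globe": result.channels["v_globe"] - m.mean["v_globe"],
        "d_v_cv": result.channels["v_cv"] - m.mean["v_cv"],
        "d_v_hv": result.channels["v_hv"] - m.mean["v_hv"],
    }


def make_fixture_waveforms(spec: dict) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic synthetic periodic trace with known beat statistics.

    spec keys: period [s], mean, amplitude (first harmonic), optional
    harmonics as [(order, amplitude, phase_rad), ...], duration [s],
    fs [Hz].  The time-weighted mean over whole periods equals ``mean``;
    with a single harmonic the pulse is exactly 2*amplitude.
    """
    period = spec["period"]
    fs = spec.get("fs", 200.0)
    dur = spec.get("duration", 10 * period)
    t = np.arange(0.0, dur, 1.0 / fs)
    x = np.full_like(t, float(spec.get("mean", 0.0)))
    x += spec.get("amplitude", 0.0) * np.sin(2 * np.pi * t / period)
    for order, amp, ph in spec.get("harmonics", []):
        x += amp * np.sin(2 * np.pi * order * t / period + ph)
    return t, x


# ---------------------------------------------------------------------------
# Validation against the packaged reference table
# ---------------------------------------------------------------------------

def load_reference(path: str | None = None) -> pd.DataFrame:
    if path is None:
        with resources.files("tiltsim.data").joinpath("reference_values.csv").open() as f:
            return pd.read_csv(f)
    return pd.read_csv(path)


def _metric_value(metrics: BeatMetrics, channel: str, kind: str) -> float:
    if channel == "hr":
        return metrics.hr
    if channel == "sv":
        return metrics.sv
    if channel == "co":
        return metrics.co
    if kind == "pulse":
        return metrics.pulse[channel]
    return metrics.mean[channel]


def validation_report(pre: BeatMetrics, post: BeatMetrics,
                      reference: pd.DataFrame | None = None,
                      outdir: str | None = None) -> pd.DataFrame:
    """Tabulate simulated steady-state values against the reference table.

    For each reference row the simulated pre/post values, absolute and
    percentage deviations, and a direction-of-change agreement flag are
    reported.  Rows whose channel is missing from the metrics are skipped
    with a warning column note.
    """
    import warnings
    ref = load_reference() if reference is None else reference
    rows = []
    for r in ref.itertuples():
        try:
            sim_pre = _metric_value(pre, r.channel, r.kind)
            sim_post = _metric_value(post, r.channel, r.kind)
        except KeyError:
            warnings.warn(f"no simulated channel for reference row {r.name!r}")
            continue
        dev_pre = sim_pre - r.pre
        dev_post = sim_post - r.post
        dir_ok = np.sign(sim_post - sim_pre) == np.sign(r.post - r.pre)
        rows.append(dict(
            name=r.name, units=r.units, kind=r.kind,
            ref_pre=r.pre, sim_pre=round(sim_pre, 3), dev_pre=round(dev_pre, 3),
            pct_pre=round(100 * dev_pre / r.pre, 1) if r.pre else np.nan,
            ref_post=r.post, sim_post=round(sim_post, 3),
            dev_post=round(dev_post, 3),
            pct_post=round(100 * dev_post / r.post, 1) if r.post else np.nan,
            direction_ok=bool(dir_ok),
        ))
    df = pd.DataFrame(rows)
    if outdir:
        os.makedirs(outdir, exist_ok=True)
        df.to_csv(os.path.join(outdir, "validation.csv"), index=False)
        with open(os.path.join(outdir, "validation.txt"), "w") as f:
            f.write(format_report(df))
    return df


def format_report(df: pd.DataFrame) -> str:
    lines = [f"{'quantity':<28}{'ref pre':>9}{'sim pre':>9}{'ref post':>10}"
             f"{'sim post':>10}{'dir':>5}"]
    for r in df.itertuples():
        lines.append(f"{r.name:<28}{r.ref_pre:>9.2f}{r.sim_pre:>9.2f}"
                     f"{r.ref_post:>10.2f}{r.sim_post:>10.2f}"
                     f"{'ok' if r.direction_ok else 'X':>5}")
    n_ok = int(df["direction_ok"].sum())
    lines.append(f"direction of change agrees for {n_ok}/{len(df)} quantities")
    return "\n".join(lines)
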