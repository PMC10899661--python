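"""Closed-loop co-simulation with the full 1D arterial tree.

Operator-split coupling: each step the 1D network advances with inlet flow
from the aortic valve and terminal loads from the 0D bed/cerebral nodes,
while the 0D remainder (heart, beds, cerebral, ocular, reflexes) advances
with its arterial-tree node pressures mirrored from the 1D solution.
The reduced-tree states inside the monolithic right-hand side are
overwritten every step so the 0D half sees the 1D pressures; their own
dynamics are discarded.

A full tilt protocol in this mode runs far beyond desk scale (hours); it
exists for verification on short horizons and for users who need wave
detail.  All protocol analyses accept its output identically.
"""

from __future__ import annotations

import numpy as np

from .core import MMHG_PA, TiltProtocol, tilt_angle_at
from .arterial import load_vessel_table
from .model import (CH, NCH, S_CTRL, S_HC, iBED, iBA, iCWL, iCWR, iEHR,
                    iVT, NV, build_runtime, initial_state, _rhs)
from .params import SubjectConfig
from .solver1d import (Network1D, apply_inlet_flow, apply_terminal,
                       advance_vessel, build_network, solve_junction,
                       _pressure)


def run_protocol_1d(config: SubjectConfig, protocol: TiltProtocol,
                    settle: float = 30.0, dx: float = 2.5e-3,
                    t_max: float | None = None):
    """Run (part of) the tilt protocol with the 1D tree in the loop.

    ``t_max`` truncates the simulated protocol span (the full span takes
    hours at 1D resolution); analyses then cover only the simulated part.
    """
    from .protocol_analysis import SimulationResult

    df = load_vessel_table()
    rt = build_runtime(config)
    angle0 = protocol.segments[0][0]
    rt.y = initial_state(rt, angle0)
    a = rt.arrays
    net = build_network(df, dx=dx, gamma_tau=0.0)
    # initialize 1D tree near the 0D init pressure
    for g in net.grids.values():
        p0 = 88.0 * MMHG_PA
        s = (p0 - g.p_d) * g.a0 / g.beta + np.sqrt(g.a0)
        g.a = s * s
        g.q = np.zeros_like(g.a0)

    names = list(df["name"])
    nidx = {n: i for i, n in enumerate(names)}
    termbed = a["termbed"]
    hc = a["scal"][S_HC]
    from .solver1d import max_dt
    dt = min(config.dt, 0.8 * max_dt(list(net.grids.values())))
    duration = protocol.duration if t_max is None else min(t_max, protocol.duration)
    n_steps = int(round((settle + duration) / dt))
    sample_every = max(1, int(round(1.0 / (config.sample_hz * dt))))

    y = rt.y
    dy = np.empty_like(y)
    aux = np.empty(NCH)
    tau, T = 0.0, rt.T
    t = -settle
    beats = []
    out_t, out = [], []
    cp = a["cp"]
    r_av = a["hp"][16]

    def bed_pressure(b):
        return (y[iBED + 3 * b] - a["bVu"][b, 0]) / a["bC"][b, 0]

    for step in range(n_steps):
        ang = float(tilt_angle_at(max(t, 0.0), protocol)) if t >= 0 else angle0
        sin_a = np.sin(np.deg2rad(ang))
        # mirror 1D pressures into the reduced-tree states (local mmHg)
        itp = a["scal"][1] + a["scal"][2] * sin_a
        for i, n in enumerate(names):
            g = net.grids[n]
            p_loc = _pressure(g.a[-1], g.a0[-1], g.beta[-1], g.p_d) / MMHG_PA
            y[iVT + i] = (p_loc - a["thor"][i] * itp) * a["Ct"][i]
        # 0D half-step: full RHS, tree derivatives discarded
        _rhs(t, y, dy, aux, sin_a, tau, T, a["scal"], a["par"], a["Rt"],
             a["Lt"], a["Ct"], a["zt"], a["thor"], a["termbed"], a["zct"],
             a["bR"], a["bC"], a["bVu"], a["bZ"], a["bFl"], a["hp"], a["pp"],
             a["vcp"], a["cp"], a["ep"], a["ctl"])
        q_av = aux[CH["q_av"]]
        dy[:iVT + NV] = 0.0          # tree handled by the 1D solver
        y += dt * dy
        if step % sample_every == 0:
            out_t.append(t)
            out.append(aux.copy())
        # 1D step with the current boundary data
        for g in net.grids.values():
            advance_vessel(g, dt, sin_a=sin_a, check=False)
        apply_inlet_flow(net.grids[net.root], q_av * 1e-6)
        for n, g in net.grids.items():
            kids = net.children.get(n, [])
            if kids:
                solve_junction(g, [net.grids[k] for k in kids])
                continue
            i = nidx[n]
            tb = termbed[i]
            zt_end = a["zt"][i]
            if tb < 0:
                p_out, z_out, zc = 75.0, zt_end, a["zct"][i]
            elif tb < 6:
                p_out = bed_pressure(tb)
                z_out = a["bZ"][tb, 0]
                zc = a["zct"][i]
            elif tb == 10:
                p_out = y[iCWL] / cp[5]
                z_out, zc = cp[0], a["zct"][i]
            elif tb == 11:
                p_out = y[iCWR] / cp[5]
                z_out, zc = cp[0], a["zct"][i]
            else:
                p_out = y[iBA] / cp[6]
                z_out, zc = cp[0], a["zct"][i]
            p_out_local = p_out + hc * (z_out - zt_end) * sin_a
            apply_terminal(g, zc * MMHG_PA * 1e6, p_out_local * MMHG_PA)
        t += dt
        tau += dt
        if tau >= T:
            tau -= T
            hr = a["hp"][0] * (1.0 + y[iEHR] * a["scal"][S_CTRL])
            hr = min(max(hr, a["hr_clamp"][0]), a["hr_clamp"][1])
            T = 60.0 / hr
            if t > 0:
                beats.append(t)

    out = np.asarray(out)
    out_t = np.asarray(out_t)
    keep = out_t >= 0.0
    time = out_t[keep]
    channels = {name: out[keep, k].copy() for name, k in CH.items()
                if name != "err_flag"}
    angle = np.asarray(tilt_angle_at(time, protocol))
    return SimulationResult(time=time, channels=channels,
                            beats=np.asarray(beats), angle=angle,
                            config=config, protocol=protocol,
                            log=dict(mode="1d", dx=dx, dt=dt,
                                     settle_s=settle, n_beats=len(beats)))
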