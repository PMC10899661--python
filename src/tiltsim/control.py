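"""Short-term autonomic control: arterial baroreflex and cardiopulmonary
reflex.

The carotid-sinus afferent senses the *local* pressure at the sinus, which
sits well above the heart: upright posture therefore lowers the sensed
pressure at identical aortic pressure, which is what makes the reflex
posture-sensitive.  The cardiopulmonary afferent senses right-atrial
transmural pressure (chamber minus intrathoracic).  A shared sympathetic
drive moves four effectors (heart period, ventricular contractility,
arteriolar resistance, venous unstressed volume) through first-order
dynamics; heart rate is applied only at beat boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .params import ControlParams


@dataclass
class ReflexState:
    """Filtered afferents plus the four effector states (dimensionless
    deviations from baseline; HR in bpm is derived)."""
    p_cs_filt: float = 0.0
    p_cp_filt: float = 0.0
    e_hr: float = 0.0
    e_emax: float = 0.0
    e_res: float = 0.0
    e_vu: float = 0.0
    params: ControlParams = field(default_factory=ControlParams)

    def heart_rate(self, hr0: float) -> float:
        hr = hr0 * (1.0 + self.e_hr)
        return float(np.clip(hr, self.params.hr_min, self.params.hr_max))

    def scales(self) -> dict[str, float]:
        return dict(
            emax=max(0.2, 1.0 + self.e_emax),
            resistance=max(0.2, 1.0 + self.e_res),
            vu_fraction=self.e_vu,
        )


def afferent_drive(p_sensor: float, set_point: float, width: float) -> float:
    """Bounded, strictly increasing sigmoid of (p_sensor - set_point).

    Returns tanh((p - p_set)/width): zero at the set-point, saturating at
    +/-1.  ``width`` is the pressure scale over which the reflex saturates;
    the slope at the set-point is 1/width.
    """
    if not np.isfinite(p_sensor):
        raise ValueError("non-finite sensor pressure")
    return float(np.tanh((p_sensor - set_point) / width))


def sympathetic_drive(p_cs: float, p_cp: float, p: ControlParams) -> float:
    """Common sympathetic outflow: positive when sensed pressures are low."""
    s_b = afferent_drive(p_cs, p.p_cs_set, p.k_cs)
    s_cp = afferent_drive(p_cp, p.p_cp_set, p.k_cp)
    return -(s_b + p.w_cp * s_cp)


def effector_update(drive: float, state: ReflexState, dt: float) -> ReflexState:
    """One first-order step of every effector toward its static target.

    Each effector relaxes as de/dt = (gain*drive - e)/tau.  A step in
    ``drive`` therefore reaches 63.2% of its final change after one time
    constant.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = state.params
    def relax(e, g, tau):
        return e + dt * (g * drive - e) / tau
    return replace(
        state,
        e_hr=relax(state.e_hr, p.g_hr, p.tau_hr),
        e_emax=relax(state.e_emax, p.g_emax, p.tau_emax),
        e_res=relax(state.e_res, p.g_res, p.tau_res),
        e_vu=relax(state.e_vu, p.g_vu, p.tau_vu),
    )


def filter_afferents(state: ReflexState, p_cs: float, p_cp: float,
                     dt: float) -> ReflexState:
    """First-order low-pass of the raw sensed pressures."""
    tau = state.params.tau_afferent
    return replace(
        state,
        p_cs_filt=state.p_cs_filt + dt * (p_cs - state.p_cs_filt) / tau,
        p_cp_filt=state.p_cp_filt + dt * (p_cp - state.p_cp_filt) / tau,
    )
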