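"""Cerebrovascular module: autoregulation, CO2 reactivity, CSF dynamics,
nonlinear intracranial compliance, and a standalone fixed-boundary
integration of the cerebral network.

The network is the lumped circle of Willis (ICA siphon nodes, basilar,
MCA/ACA/PCA per side) feeding six pial territories whose resistances and
compliances are under autoregulation, a single capillary-venous branch, and
a Starling-resistor (vascular waterfall) venous outflow referenced to ICP.
ICP obeys a monoexponential craniospinal compliance C_ic = 1/(kE (ICP-p0)),
driven by CSF formation/outflow, intracranial vascular volume change, and
the posture-dependent hydrostatic CSF column.

The closed-loop solver in :mod:`tiltsim.model` inlines the same equations;
`simulate_fixed_boundaries` lets the cerebral module run on its own with
prescribed arterial/venous boundary pressures (used for autoregulation
plateau experiments).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .core import CSF, G_EARTH, MMHG_PA
from .params import CerebralParams


@dataclass
class AutoregulationState:
    """Filtered CBF deviation and CO2 activation with the resulting
    distal compliance/resistance scale factors."""
    x_aut: float = 0.0
    x_co2: float = 0.0
    c_scale: float = 1.0
    r_scale: float = 1.0


@dataclass
class CSFICPState:
    icp: float = -0.1
    qf: float = 0.0
    qo: float = 0.0


def autoreg_scales(x_aut: float, x_co2: float, p: CerebralParams,
                   enabled: bool = True) -> tuple[float, float]:
    """Sigmoidal static map from the regulatory state to (C, R) scales.

    High CBF (x_aut > 0) shrinks distal compliance and raises distal
    resistance; hypercapnia (x_co2 > 0) does the opposite.  The compliance
    scale is bounded by the tanh saturation at 1 +/- g_c.
    """
    if not enabled:
        return 1.0, 1.0
    cc = 1.0 - p.g_c * np.tanh((x_aut - x_co2) / p.x_sat)
    cc = max(cc, 0.3)
    return cc, (1.0 / cc) ** p.kappa_r


def autoregulation_update(cbf_filtered: float, state: AutoregulationState,
                          dt: float, p: CerebralParams) -> AutoregulationState:
    """First-order update of the autoregulation state from filtered CBF.

    dx/dt = (g_aut (CBF - CBF_n)/CBF_n - x)/tau_aut.
    """
    if not p.cbf_n > 0:
        raise ValueError("nominal CBF must be positive")
    target = p.g_aut * (cbf_filtered - p.cbf_n) / p.cbf_n
    x = state.x_aut + dt * (target - state.x_aut) / p.tau_aut
    cc, rr = autoreg_scales(x, state.x_co2, p)
    return replace(state, x_aut=x, c_scale=cc, r_scale=rr)


def co2_activation(paco2: float, state: AutoregulationState, dt: float,
                   p: CerebralParams) -> AutoregulationState:
    """First-order filtered logarithmic CO2 reactivity: zero at nominal
    PaCO2; hypercapnia gives x_co2 > 0 (vasodilation)."""
    if not paco2 > 0:
        raise ValueError("PaCO2 must be positive")
    target = p.g_co2 * np.log(paco2 / p.paco2_n)
    x = state.x_co2 + dt * (target - state.x_co2) / p.tau_co2
    cc, rr = autoreg_scales(state.x_aut, x, p)
    return replace(state, x_co2=x, c_scale=cc, r_scale=rr)


def csf_flows(p_ccap: float, icp: float, p_dvs: float,
              rf: float, ro: float) -> tuple[float, float]:
    """Unidirectional CSF formation and outflow rates [ml/s]: formation
    from the cerebral capillaries into the CSF space, absorption through
    the arachnoid granulations into the dural sinus; both rectified."""
    if not (rf > 0 and ro > 0):
        raise ValueError("CSF resistances must be positive")
    qf = max(0.0, (p_ccap - icp) / rf)
    qo = max(0.0, (icp - p_dvs) / ro)
    return qf, qo


def intracranial_compliance(icp: float, p: CerebralParams) -> float:
    """Monoexponential craniospinal law C_ic = 1/(kE (ICP - p_ic0));
    strictly decreasing in ICP over the validity range."""
    if not (p.icp_min <= icp <= p.icp_max):
        raise ValueError(f"ICP {icp} outside compliance-law domain "
                         f"[{p.icp_min}, {p.icp_max}]")
    c = 1.0 / (p.k_e * (icp - p.p_ic0))
    if c <= 0.0:
        raise ValueError("compliance law evaluated below its pressure offset")
    return c


def spinal_column(p: CerebralParams) -> float:
    """Head-to-lumbar hydrostatic CSF column [mmHg per unit sin(alpha)]."""
    return CSF.density * G_EARTH * p.h_spinal / MMHG_PA


def icp_from_volume(v_stored: float, sin_a: float, p: CerebralParams,
                    v_ref: float = 0.0, sin_ref: float | None = None) -> float:
    """ICP as a state function of stored craniospinal volume and posture.

    Solves V_cranial(ICP) + C_sp (ICP + col_sp sin(alpha)) = v_stored,
    where the cranial store has the monoexponential elastance
    dV/dICP = 1/(kE (ICP - p_ic0)) and the spinal dural sac is a linear
    compliance whose local pressure carries the head-to-lumbar column.
    Tilting therefore redistributes CSF between skull and sac at constant
    volume - the mechanism that moves ICP with posture.
    """
    if sin_ref is None:
        sin_ref = np.sin(np.deg2rad(p.alpha_ref))
    col = spinal_column(p)
    b = p.icp_ref - p.p_ic0
    x = v_stored - v_ref
    dsin = sin_a - sin_ref
    icp = p.icp_ref
    for _ in range(60):
        f = (np.log((icp - p.p_ic0) / b) / p.k_e
             + p.c_sp * (icp - p.icp_ref) + p.c_sp * col * dsin - x)
        fp = 1.0 / (p.k_e * (icp - p.p_ic0)) + p.c_sp
        step = f / fp
        icp_n = icp - step
        if icp_n <= p.p_ic0:
            icp_n = 0.5 * (icp + p.p_ic0 + 1e-9)
        if abs(icp_n - icp) < 1e-13:
            icp = icp_n
            break
        icp = icp_n
    return float(icp)


def effective_compliance(icp: float, p: CerebralParams) -> float:
    """Total craniospinal compliance seen from the head: cranial
    monoexponential store plus the spinal sac."""
    return intracranial_compliance(icp, p) + p.c_sp


def icp_rhs(state: CSFICPState, net_vascular_rate: float, p: CerebralParams,
            angle: float = 0.0, angle_rate: float = 0.0) -> float:
    """dICP/dt [mmHg/s] at the cranial measurement site.

    Volume balance (CSF formation - outflow + intracranial vascular volume
    rate) through the total craniospinal compliance, plus the posture term:
    tilting shifts CSF into or out of the spinal sac, so at constant volume
    dICP/dt = -[C_sp col_sp/(C_cr + C_sp)] cos(alpha) d(alpha)/dt.
    At fixed posture with zero net inflow the derivative is exactly zero.
    """
    c_cr = intracranial_compliance(state.icp, p)
    c_tot = c_cr + p.c_sp
    vol_term = (state.qf - state.qo + net_vascular_rate) / c_tot
    # angle_rate in deg/s; d(sin a)/dt = cos(a) * a_dot[rad/s]
    col_eff = spinal_column(p) * p.c_sp / c_tot
    col_term = -col_eff * np.cos(np.deg2rad(angle)) * np.deg2rad(angle_rate)
    return vol_term + col_term


def icp_volume_rhs(icp: float, net_inflow: float, p: CerebralParams) -> float:
    """dICP/dt of a pure craniospinal compliance element receiving
    ``net_inflow`` [ml/s] at fixed posture (closed-form testable)."""
    return net_inflow / intracranial_compliance(icp, p)


def icp_closed_form(icp0: float, q: float, t: float | np.ndarray,
                    p: CerebralParams):
    """Analytic ICP(t) for constant net inflow q into the pure cranial
    element C_ic = 1/(kE (p-p0)): d(icp)/dt = q kE (icp - p0) gives
    exponential growth from icp0 (oracle for the elastance law)."""
    t = np.asarray(t, dtype=float)
    return p.p_ic0 + (icp0 - p.p_ic0) * np.exp(q * p.k_e * t)


@dataclass
class CerebralBoundary:
    """Fixed boundary conditions for the standalone cerebral network."""
    p_ica_l: float = 65.8
    p_ica_r: float = 65.8
    p_vert: float = 65.8
    p_svc: float = -0.5
    angle: float = 80.0


@dataclass
class CerebralSteadyState:
    cbf: float = 0.0
    icp: float = 0.0
    pressures: dict = field(default_factory=dict)
    autoreg: AutoregulationState = field(default_factory=AutoregulationState)


def simulate_fixed_boundaries(bound: CerebralBoundary,
                              p: CerebralParams | None = None,
                              t_end: float = 300.0,
                              autoregulation: bool = True,
                              paco2: float = 40.0,
                              freeze_icp: bool = False) -> CerebralSteadyState:
    """Integrate the cerebral network to steady state with fixed boundaries.

    State: [v_cw_l, v_cw_r, v_ba, v_w(6), v_d(6), v_ccap, v_cv, v_dvs,
    p_ic, x_cbf, x_aut, x_co2].  Uses the same laws as the closed loop,
    with the arterial boundaries applied through the terminal impedances.
    """
    p = p or CerebralParams()
    sin_a = np.sin(np.deg2rad(bound.angle))
    hc = 1050.0 * G_EARTH / MMHG_PA

    r_d1 = np.array([p.r_d1_a, p.r_d1_m, p.r_d1_p])
    r_d2 = np.array([p.r_d2_a, p.r_d2_m, p.r_d2_p])
    c_d = np.array([p.c_dist_a, p.c_dist_m, p.c_dist_p])
    w_of_d = np.array([2, 0, 4, 3, 1, 5])

    c_d6 = np.take(c_d, [0, 1, 2, 0, 1, 2])
    v_vasc_ref = (2.0 * np.sum(p.vu_dist + 37.0 * c_d)
                  + p.vu_ccap + 14.4 * p.c_ccap
                  + p.vu_cv + np.log(4.3 / p.p_cv1 + 1.0) / p.k_cv)

    def rhs(t, y):
        (v_cw_l, v_cw_r, v_ba) = y[0:3]
        v_w = y[3:9]
        v_d = y[9:15]
        v_ccap, v_cv, v_dvs, v_csf, x_cbf, x_aut, x_co2 = y[15:22]
        v_vasc = v_ccap + v_cv + np.sum(v_d)
        icp = icp_from_volume(v_csf + v_vasc - v_vasc_ref, sin_a, p)
        cc, rr = autoreg_scales(x_aut, x_co2, p, enabled=autoregulation)
        p_cw_l = v_cw_l / p.c_cw
        p_cw_r = v_cw_r / p.c_cw
        p_ba = v_ba / p.c_ba
        p_w = v_w / p.c_willis + icp
        p_d = (v_d - p.vu_dist) / (c_d6 * cc) + icp
        p_ccap = (v_ccap - p.vu_ccap) / p.c_ccap + icp
        p_cv = p.p_cv1 * (np.exp(p.k_cv * (v_cv - p.vu_cv)) - 1.0) + icp
        p_dvs = (v_dvs - p.vu_dvs) / p.c_dvs

        dy = np.zeros_like(y)
        q_in_l = (bound.p_ica_l - p_cw_l) / p.zc_ica
        q_in_r = (bound.p_ica_r - p_cw_r) / p.zc_ica
        q_in_b = 2.0 * (bound.p_vert - p_ba) / p.zc_vert
        q_cw = np.array([(p_cw_l - p_w[0]) / p.r_cw_mca,
                         (p_cw_r - p_w[1]) / p.r_cw_mca,
                         (p_cw_l - p_w[2]) / p.r_cw_aca,
                         (p_cw_r - p_w[3]) / p.r_cw_aca,
                         (p_ba - p_w[4]) / p.r_ba_pca,
                         (p_ba - p_w[5]) / p.r_ba_pca])
        q_pcoa_l = (p_cw_l - p_w[4]) / p.r_pcoa
        q_pcoa_r = (p_cw_r - p_w[5]) / p.r_pcoa
        q_acoa = (p_w[2] - p_w[3]) / p.r_acoa
        dy[0] = q_in_l - q_cw[0] - q_cw[2] - q_pcoa_l
        dy[1] = q_in_r - q_cw[1] - q_cw[3] - q_pcoa_r
        dy[2] = q_in_b - q_cw[4] - q_cw[5]
        dy[3:9] = q_cw
        dy[3 + 2] -= q_acoa
        dy[3 + 3] += q_acoa
        dy[3 + 4] += q_pcoa_l
        dy[3 + 5] += q_pcoa_r
        cbf = 0.0
        for k in range(6):
            terr = k % 3
            qin = (p_w[w_of_d[k]] - p_d[k]) / (r_d1[terr] * rr)
            qout = (p_d[k] - p_ccap) / (r_d2[terr] * rr)
            dy[3 + w_of_d[k]] -= qin
            dy[9 + k] += qin - qout
            dy[15] += qout
            cbf += qout
        for side in range(2):
            o = 9 + 3 * side
            q1 = (p_d[3 * side] - p_d[3 * side + 1]) / p.r_collateral
            q2 = (p_d[3 * side + 1] - p_d[3 * side + 2]) / p.r_collateral
            dy[o] -= q1
            dy[o + 1] += q1 - q2
            dy[o + 2] += q2
        q_ccap_cv = (p_ccap - p_cv) / p.r_ccap_cv
        q_cv_out = (p_cv - max(icp, p_dvs)) / p.r_vs
        phi_dvs = p_dvs + hc * p.z_dvs * sin_a
        phi_svc = bound.p_svc + hc * 0.035 * sin_a
        q_dvs_svc = (phi_dvs - phi_svc) / p.r_dvs_svc
        dy[15] -= q_ccap_cv
        dy[16] = q_ccap_cv - q_cv_out
        dy[17] = q_cv_out - q_dvs_svc
        qf, qo = csf_flows(p_ccap, icp, p_dvs, p.r_f, p.r_o)
        dy[15] -= qf
        dy[17] += qo
        if freeze_icp:
            dy[18] = 0.0
        else:
            dy[18] = qf - qo
        dy[19] = (cbf - x_cbf) / p.tau_cbf
        dy[20] = (p.g_aut * (x_cbf - p.cbf_n) / p.cbf_n - x_aut) / p.tau_aut
        dy[21] = (p.g_co2 * np.log(paco2 / p.paco2_n) - x_co2) / p.tau_co2
        return dy

    y0 = np.zeros(22)
    y0[0] = 65.0 * p.c_cw
    y0[1] = 65.0 * p.c_cw
    y0[2] = 65.0 * p.c_ba
    y0[3:9] = 63.0 * p.c_willis
    y0[9:15] = p.vu_dist + 37.0 * np.take(c_d, [0, 1, 2, 0, 1, 2])
    y0[15] = p.vu_ccap + 14.4 * p.c_ccap
    y0[16] = p.vu_cv + np.log(4.3 / p.p_cv1 + 1.0) / p.k_cv
    y0[17] = p.vu_dvs - 10.5 * p.c_dvs
    y0[18] = 0.0
    y0[19] = p.cbf_n
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA",
                    rtol=1e-8, atol=1e-10)
    y = sol.y[:, -1]
    v_vasc = y[15] + y[16] + np.sum(y[9:15])
    icp = icp_from_volume(y[18] + v_vasc - v_vasc_ref, sin_a, p)
    cc, rr = autoreg_scales(y[20], y[21], p, enabled=autoregulation)
    p_w = y[3:9] / p.c_willis + icp
    p_d = (y[9:15] - p.vu_dist) / (np.take(c_d, [0, 1, 2, 0, 1, 2]) * cc) + icp
    p_ccap = (y[15] - p.vu_ccap) / p.c_ccap + icp
    cbf = float(np.sum((p_d - p_ccap) / (np.take(r_d2, [0, 1, 2, 0, 1, 2]) * rr)))
    st = CerebralSteadyState(
        cbf=cbf, icp=float(icp),
        pressures=dict(
            cw_l=float(y[0] / p.c_cw), cw_r=float(y[1] / p.c_cw),
            mca_l=float(p_w[0]), mca_r=float(p_w[1]),
            dm_l=float(p_d[1]), dm_r=float(p_d[4]), ccap=float(p_ccap),
            cv=float(p.p_cv1 * (np.exp(p.k_cv * (y[16] - p.vu_cv)) - 1.0) + icp),
            dvs=float((y[17] - p.vu_dvs) / p.c_dvs)),
        autoreg=AutoregulationState(x_aut=float(y[20]), x_co2=float(y[21]),
                                    c_scale=cc, r_scale=rr))
    return st
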