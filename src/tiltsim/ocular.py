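"""Six-compartment lumped eye model: boundary pressures at eye level,
intraocular pressure, globe volume, aqueous humor dynamics, and the derived
translaminar and ocular perfusion pressures.

Per eye the compartments are: ocular arterial, choroid/capillary, ocular
venous, aqueous chamber, the globe envelope (a Friedenwald-type
exponential wall law relating intraocular pressure to total contents
volume), and the retrobulbar interface through which a fraction of ICP
loads the globe exterior.  Two symmetric eyes are simulated as one doubled
compartment fed by both internal carotids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import BLOOD, BodyGeometry, hydrostatic_delta_p
from .params import OcularParams


@dataclass
class EyeBoundary:
    """Arterial/venous pressure at eye level plus ICP [mmHg]."""
    pa_eye: float
    pv_eye: float
    icp: float

    def __post_init__(self) -> None:
        for v in (self.pa_eye, self.pv_eye, self.icp):
            if not np.isfinite(v):
                raise ValueError("non-finite eye boundary pressure")


@dataclass
class EyeState:
    """Volumes [ml] of the intraocular compartments (per eye) and the
    resulting pressures; IOP follows algebraically from the wall law."""
    v_arterial: float
    v_choroid: float
    v_venous: float
    v_aqueous: float
    iop: float = 0.0
    q_aq_in: float = 0.0
    q_aq_out: float = 0.0

    @property
    def v_globe(self) -> float:
        return self.v_arterial + self.v_choroid + self.v_venous + self.v_aqueous


def eye_boundary_pressures(p_ica: float, p_venous: float, angle: float,
                           geometry: BodyGeometry, icp: float = 0.0,
                           ocular: OcularParams | None = None) -> EyeBoundary:
    """Boundary pressures at the globe from the carotid and venous levels.

    The arterial side carries the full hydrostatic offset of the globe: an
    axial part (along the body axis, sin term) plus the anterior offset from
    the mid-coronal plane (cos term) - so near-horizontal postures still
    see a small eye-elevation correction that fully upright postures do not
    (cos 90 = 0).  The venous reference is the collapse-limited drainage
    pressure (episcleral/jugular pathway), whose effective column is
    absorbed in the calibrated drainage-node elevation, so it passes
    through unchanged here.
    """
    o = ocular or OcularParams()
    dz_ax = o.z_eye_axial - geometry.axial_position["head"]
    dp = hydrostatic_delta_p(dz_ax, geometry.eye_anterior_offset, angle, BLOOD)
    return EyeBoundary(pa_eye=p_ica - dp, pv_eye=p_venous, icp=icp)


def tlp(iop: float, icp: float) -> float:
    """Translaminar pressure across the lamina cribrosa: IOP - ICP [mmHg]."""
    return iop - icp


def opp(pa_eye: float, iop: float) -> float:
    """Ocular perfusion pressure: arterial pressure at eye level - IOP."""
    return pa_eye - iop


def wall_pressure(v_globe: float, icp: float, o: OcularParams) -> float:
    """IOP from the globe envelope: exponential (Friedenwald-type) wall law
    on total contents volume, on top of the retrobulbar orbit pressure."""
    p_orbit = o.orbit_gamma * icp + o.orbit_p0
    return p_orbit + o.iop_ref * np.exp(o.rigidity * (v_globe - o.vg_ref))


def aqueous_flows(iop: float, p_choroid: float, p_ev: float, icp: float,
                  o: OcularParams) -> tuple[float, float]:
    """(inflow, outflow) of aqueous humor [ml/s] per eye.

    Inflow: constant active secretion plus pressure-dependent
    ultrafiltration from the choroid/ciliary circulation.  Outflow:
    trabecular (against episcleral venous pressure) plus uveoscleral
    (against the orbit), both rectified.
    """
    p_orbit = o.orbit_gamma * icp + o.orbit_p0
    q_in = o.q_secr + max(0.0, (p_choroid - iop)) / o.r_uf
    q_tm = max(0.0, iop - (p_ev + o.evp_offset)) / o.r_tm
    q_uv = max(0.0, iop - p_orbit) / o.r_uv
    return q_in, q_tm + q_uv


def ocular_rhs(state: EyeState, bound: EyeBoundary,
               o: OcularParams | None = None) -> tuple[np.ndarray, EyeState]:
    """Mass-conservative derivatives of the four volume states (per eye).

    Returns (dV/dt array for [arterial, choroid, venous, aqueous], and the
    state with IOP/aqueous flows filled in).  With all compartment
    pressures equal and matching boundaries, all flows vanish.
    """
    o = o or OcularParams()
    iop = wall_pressure(state.v_globe, bound.icp, o)
    p_oa = (state.v_arterial - o.vu_oa) / o.c_oa + iop
    p_ch = (state.v_choroid - o.vu_ch) / o.c_ch + iop
    p_ov = (state.v_venous - o.vu_ov) / o.c_ov + iop
    q_in = (bound.pa_eye - p_oa) / o.r_in
    q_a2 = (p_oa - p_ch) / o.r_a2
    q_v1 = (p_ch - p_ov) / o.r_v1
    q_v2 = (p_ov - bound.pv_eye) / o.r_v2
    q_aq_in, q_aq_out = aqueous_flows(iop, p_ch, bound.pv_eye, bound.icp, o)
    dv = np.array([
        q_in - q_a2,
        q_a2 - q_v1 - q_aq_in,
        q_v1 - q_v2,
        q_aq_in - q_aq_out,
    ])
    new = EyeState(state.v_arterial, state.v_choroid, state.v_venous,
                   state.v_aqueous, iop=iop, q_aq_in=q_aq_in, q_aq_out=q_aq_out)
    return dv, new


def equilibrium_state(bound: EyeBoundary, o: OcularParams | None = None,
                      iop: float | None = None) -> EyeState:
    """Flow-consistent vascular volumes at a prescribed (or reference) IOP."""
    o = o or OcularParams()
    iop = o.iop_ref if iop is None else iop
    q = (bound.pa_eye - bound.pv_eye) / (o.r_in + o.r_a2 + o.r_v1 + o.r_v2)
    p_oa = bound.pa_eye - o.r_in * q
    p_ch = p_oa - o.r_a2 * q
    p_ov = p_ch - o.r_v1 * q
    v_oa = o.vu_oa + (p_oa - iop) * o.c_oa
    v_ch = o.vu_ch + (p_ch - iop) * o.c_ch
    v_ov = o.vu_ov + (p_ov - iop) * o.c_ov
    v_aq = o.vg_ref - (v_oa + v_ch + v_ov)
    return EyeState(v_oa, v_ch, v_ov, v_aq, iop=iop)
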