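"""Subject parameter configuration for the closed-loop simulator.

All pressures are mmHg, volumes ml, times s, resistances mmHg s/ml,
compliances ml/mmHg, elastances mmHg/ml, elevations m (positive toward the
head, heart level = 0).  The defaults describe the generic healthy subject
(25 yo, 75 kg, 175 cm male) the model is calibrated on.

The lumped compartment elevations are *effective* heights: they are chosen so
that the hydrostatic columns reproduce physiological posture responses (e.g.
the collapse-limited behaviour of the jugular pathway is encoded as a small
effective superior-vena-cava elevation rather than an anatomical one).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

from .core import BodyGeometry, TiltProtocol


@dataclass
class HeartParams:
    """Four time-varying elastance chambers plus valves.

    Ventricular activation: cosine contraction/relaxation with systolic
    duration scaling as sqrt(T); atrial systole precedes ventricular onset by
    ``av_delay``.
    """
    hr0: float = 72.0          # intrinsic rate at the reflex set-point [bpm]
    # chamber: (Emin, Emax, V0)
    ra: tuple[float, float, float] = (0.05, 0.15, 14.0)
    rv: tuple[float, float, float] = (0.05, 0.75, 16.0)
    la: tuple[float, float, float] = (0.09, 0.25, 10.0)
    lv: tuple[float, float, float] = (0.09, 2.80, 20.0)
    r_tricuspid: float = 0.003
    r_pulmonic: float = 0.0035
    r_mitral: float = 0.004
    r_aortic: float = 0.006
    tvc_scale: float = 0.30    # ventricular contraction time = tvc_scale*sqrt(T)
    tvr_scale: float = 0.16    # relaxation
    k_dia_rv: float = 7.0e-6   # cubic diastolic stiffening [mmHg/ml^3]
    k_dia_lv: float = 9.3e-6
    tac_scale: float = 0.10    # atrial pulse duration = tac_base + tac_scale*sqrt(T)
    tac_base: float = 0.10
    av_delay: float = 0.12


@dataclass
class PulmonaryParams:
    c_pa: float = 4.0
    c_pv: float = 15.0
    r_pulm: float = 0.055
    r_pv_la: float = 0.004
    vu_pa: float = 120.0
    vu_pv: float = 320.0


@dataclass
class BedParams:
    """One regional microvascular bed: arterioles -> capillaries/venules ->
    veins -> vena cava, with optional venous valves."""
    name: str = ""
    r_art: float = 10.0
    r_ven: float = 1.5
    r_out: float = 0.5
    c_art: float = 0.10
    c_cap: float = 0.40
    c_vein: float = 4.0
    vu_art: float = 20.0
    vu_cap: float = 40.0
    vu_vein: float = 150.0
    z_art: float = 0.0          # effective elevation [m]
    z_cap: float = 0.0
    z_vein: float = 0.0
    has_valve: bool = False     # venous valve at the outflow
    drains_to: str = "svc"      # 'svc' or 'ivc'
    reflex_r: bool = True       # arteriolar R under autonomic control
    reflex_vu: bool = False     # venous unstressed volume under control


def _default_beds() -> dict[str, BedParams]:
    return {
        "head_ec": BedParams(name="head_ec", r_art=7.65, r_ven=1.5, r_out=0.5,
                             c_art=0.10, c_cap=0.35, c_vein=3.5,
                             vu_art=15, vu_cap=35, vu_vein=120,
                             z_art=0.30, z_cap=0.30, z_vein=0.30,
                             drains_to="svc", reflex_r=True),
        "arms": BedParams(name="arms", r_art=7.65, r_ven=1.5, r_out=0.5,
                          c_art=0.10, c_cap=0.40, c_vein=4.0,
                          vu_art=20, vu_cap=40, vu_vein=200,
                          z_art=-0.25, z_cap=-0.25, z_vein=-0.25,
                          has_valve=True, drains_to="svc",
                          reflex_r=True, reflex_vu=True),
        "coronary": BedParams(name="coronary", r_art=13.8, r_ven=3.0, r_out=0.5,
                              c_art=0.03, c_cap=0.10, c_vein=0.8,
                              vu_art=8, vu_cap=15, vu_vein=30,
                              z_art=0.0, z_cap=0.0, z_vein=0.0,
                              drains_to="svc", reflex_r=False),
        "upper_abd": BedParams(name="upper_abd", r_art=1.74, r_ven=0.40, r_out=0.15,
                               c_art=0.30, c_cap=1.40, c_vein=14.0,
                               vu_art=60, vu_cap=140, vu_vein=700,
                               z_art=-0.12, z_cap=-0.12, z_vein=-0.12,
                               drains_to="ivc", reflex_r=True, reflex_vu=True),
        "lower_abd": BedParams(name="lower_abd", r_art=4.32, r_ven=1.0, r_out=0.3,
                               c_art=0.12, c_cap=0.60, c_vein=7.0,
                               vu_art=30, vu_cap=60, vu_vein=300,
                               z_art=-0.25, z_cap=-0.25, z_vein=-0.25,
                               drains_to="ivc", reflex_r=True, reflex_vu=True),
        "legs": BedParams(name="legs", r_art=3.54, r_ven=0.7, r_out=0.3,
                          c_art=0.15, c_cap=0.70, c_vein=9.0,
                          vu_art=40, vu_cap=80, vu_vein=400,
                          z_art=-0.62, z_cap=-0.62, z_vein=-0.62,
                          has_valve=True, drains_to="ivc",
                          reflex_r=True, reflex_vu=True),
    }


@dataclass
class VenaCavaParams:
    c_svc: float = 1.5
    c_ivc: float = 4.0
    vu_svc: float = 60.0
    vu_ivc: float = 180.0
    z_svc: float = 0.035        # effective centroid (collapse-limited upright)
    z_ivc: float = -0.09
    r_svc_ra: float = 0.01
    r_ivc_ra: float = 0.006


@dataclass
class ItpParams:
    """Intrathoracic pressure, linear in sin(alpha)."""
    supine: float = -4.0
    upright: float = -6.5


@dataclass
class CerebralParams:
    """Circle of Willis + pial territories + capillary-venous branch + CSF.

    Distal resistances/compliances are under autoregulation and CO2
    reactivity.  The cerebral venous outflow is a Starling resistor
    (vascular waterfall) referenced to ICP.
    """
    z_head: float = 0.345        # intracranial node elevation
    z_dvs: float = 0.17          # effective dural venous sinus elevation
    # Willis large-artery resistances (per side where l/r)
    r_cw_mca: float = 0.44
    r_cw_aca: float = 1.6
    r_ba_pca: float = 1.6
    r_pcoa: float = 40.0         # posterior communicating (collateral)
    r_acoa: float = 20.0         # anterior communicating
    c_willis: float = 0.004      # small node compliances
    c_cw: float = 0.008
    c_ba: float = 0.006
    zc_ica: float = 0.2          # terminal coupling ICA -> siphon node
    zc_vert: float = 0.5
    # distal (pial) territories: nominal pressures calibrated at 80 deg HUT
    # per-territory ladders: R_d1 willis->distal, R_d2 distal->capillary
    r_d1_m: float = 7.89
    r_d2_m: float = 6.48
    r_d1_a: float = 22.1
    r_d2_a: float = 18.4
    r_d1_p: float = 22.1
    r_d2_p: float = 18.4
    c_dist_m: float = 0.012      # per middle territory
    c_dist_a: float = 0.004
    c_dist_p: float = 0.004
    vu_dist: float = 2.0         # per territory
    r_collateral: float = 30.0   # cortical collaterals between territories
    # capillary / venous
    c_ccap: float = 0.30
    vu_ccap: float = 6.0
    r_ccap_cv: float = 0.88
    k_cv: float = 0.30           # venous compliance 1/(k (p_cv - icp + p_cv1))
    p_cv1: float = 2.5
    vu_cv: float = 60.0
    r_vs: float = 0.366          # Starling (bridge-vein) resistance
    c_dvs: float = 0.25
    vu_dvs: float = 12.0
    r_dvs_svc: float = 0.016
    # autoregulation & CO2
    cbf_n: float = 11.63         # set-point total CBF [ml/s]
    tau_cbf: float = 3.0         # afferent flow filter
    tau_aut: float = 20.0
    g_aut: float = 1.0           # loop gain on normalized CBF error
    x_sat: float = 0.12          # tanh scale of the sigmoid
    g_c: float = 0.35            # max fractional compliance change
    kappa_r: float = 0.66        # R_d ~ (C_dn/C_d)^kappa
    tau_co2: float = 40.0
    g_co2: float = 6.0
    paco2_n: float = 40.0
    # CSF / ICP
    r_f: float = 67000.0         # formation
    r_o: float = 47350.0         # outflow (arachnoid granulations)
    k_e: float = 0.085           # craniospinal elastance coefficient [1/ml]
    p_ic0: float = -6.0          # compliance-law offset
    icp_ref: float = -0.1        # ICP at reference volume and posture
    alpha_ref: float = 80.0      # reference posture for the CSF store [deg]
    c_sp: float = 0.369          # spinal dural sac compliance [ml/mmHg]
    h_spinal: float = 0.55       # head-to-lumbar CSF column [m]
    tau_redistribution: float = 12.0   # craniospinal CSF shift lag [s]
    icp_min: float = -12.0       # compliance-law validity
    icp_max: float = 60.0


@dataclass
class OcularParams:
    """Six-compartment eye (per eye; two symmetric eyes simulated as one
    doubled compartment drawing from both internal carotids)."""
    z_eye_axial: float = 0.3452      # axial elevation of the globe
    d_anterior: float = 0.0286       # anterior offset from mid-coronal plane
    r_in: float = 700.0              # pa_eye -> ocular arterial
    r_a2: float = 1100.0             # arterial -> choroid/capillary
    r_v1: float = 950.0              # choroid -> ocular venous
    r_v2: float = 350.0              # ocular venous -> eye drainage node
    c_oa: float = 0.0004
    c_ch: float = 0.0008
    c_ov: float = 0.0008
    vu_oa: float = 0.12
    vu_ch: float = 0.30
    vu_ov: float = 0.25
    # aqueous humor
    q_secr: float = 1.49e-4          # net aqueous turnover [ml/s]
    r_uf: float = 1.0e7              # ultrafiltration resistance
    r_tm: float = 1.33e5             # trabecular outflow
    r_uv: float = 1.56e5             # uveoscleral outflow
    evp_offset: float = 7.0          # episcleral venous p = pv_eye + offset
    # globe envelope (Friedenwald-type)
    rigidity: float = 46.0           # dIOP/dV = rigidity*(IOP-p_orbit) [1/ml]
    iop_ref: float = 15.8            # wall tension at reference volume
    orbit_gamma: float = 0.15        # retrobulbar coupling of ICP
    orbit_p0: float = 0.0
    vg_ref: float = 6.5              # reference globe volume [ml]
    # eye venous drainage node
    c_ev: float = 0.30
    vu_ev: float = 3.0
    z_ev: float = 0.0                # collapse-limited effective elevation
    r_ev_svc: float = 2.0


@dataclass
class ControlParams:
    """Arterial baroreflex + cardiopulmonary reflex.

    Afferents: carotid-sinus local pressure (includes its hydrostatic
    elevation via the arterial tree) and right-atrial transmural pressure.
    A common sympathetic drive plus vagal HR control; first-order effector
    dynamics; HR applied at beat boundaries.
    """
    enabled: bool = True
    tau_afferent: float = 2.0
    p_cs_set: float = 79.9       # carotid sinus set-point (calibrated at 80 HUT)
    k_cs: float = 12.0           # sigmoid width
    p_cp_set: float = 8.10        # RA transmural set-point
    k_cp: float = 4.0
    w_cp: float = 0.4            # weight of cardiopulmonary afferent
    g_hr: float = 0.055
    g_emax: float = 0.20
    g_res: float = 0.29
    g_vu: float = 0.25           # fractional venous unstressed-volume swing
    tau_hr: float = 3.0
    tau_emax: float = 8.0
    tau_res: float = 6.0
    tau_vu: float = 15.0
    hr_min: float = 30.0
    hr_max: float = 200.0


@dataclass
class SubjectConfig:
    """Complete parameter set for one simulated subject."""
    heart: HeartParams = field(default_factory=HeartParams)
    pulmonary: PulmonaryParams = field(default_factory=PulmonaryParams)
    beds: dict[str, BedParams] = field(default_factory=_default_beds)
    vena_cava: VenaCavaParams = field(default_factory=VenaCavaParams)
    itp: ItpParams = field(default_factory=ItpParams)
    cerebral: CerebralParams = field(default_factory=CerebralParams)
    ocular: OcularParams = field(default_factory=OcularParams)
    control: ControlParams = field(default_factory=ControlParams)
    geometry: BodyGeometry = field(default_factory=BodyGeometry)
    total_blood_volume: float = 5260.0
    stiffness_scale: float = 1.0     # global arterial wall-stiffness factor
    autoregulation: bool = True
    paco2: float = 40.0
    dt: float = 2.5e-4
    sample_hz: float = 200.0

    def to_dict(self) -> dict[str, Any]:
        def conv(o):
            if dataclasses.is_dataclass(o):
                return {k: conv(v) for k, v in dataclasses.asdict(o).items()}
            if isinstance(o, dict):
                return {k: conv(v) for k, v in o.items()}
            if isinstance(o, tuple):
                return list(o)
            return o
        return conv(self)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "SubjectConfig":
        with open(path) as f:
            d = yaml.safe_load(f)
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SubjectConfig":
        kw: dict[str, Any] = {}
        sub = {
            "heart": HeartParams, "pulmonary": PulmonaryParams,
            "vena_cava": VenaCavaParams, "itp": ItpParams,
            "cerebral": CerebralParams, "ocular": OcularParams,
            "control": ControlParams,
        }
        for k, v in (d or {}).items():
            if k in sub:
                fields = {f.name for f in dataclasses.fields(sub[k])}
                args = {a: (tuple(b) if isinstance(b, list) else b)
                        for a, b in v.items() if a in fields}
                kw[k] = sub[k](**args)
            elif k == "beds":
                kw[k] = {name: BedParams(**bv) for name, bv in v.items()}
            elif k == "geometry":
                kw[k] = BodyGeometry(
                    axial_position=dict(v.get("axial_position", {})),
                    eye_anterior_offset=v.get("eye_anterior_offset", 0.0286),
                    svc_head_distance=v.get("svc_head_distance", 0.135))
            elif k in {f.name for f in dataclasses.fields(cls)}:
                kw[k] = v
        return cls(**kw)
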