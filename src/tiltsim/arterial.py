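"""The 1D arterial tree: geometry, visco-elastic tube law, terminal coupling,
and the reduced-order (R-L-C chain) fallback used for desk-scale protocol runs.

The tree is described by a packaged CSV table (63 tapered vessels).  Each
vessel carries a reference wave speed ``c0`` at its reference area, from which
the elastic stiffness ``beta = 2 rho c0^2 sqrt(A0)`` of the tube law

    p = p_ref + (beta / A0) (sqrt(A) - sqrt(A0)) + gamma / A0^{3/2} dA/dt + p_ext

is derived (pressures in Pa inside the 1D solver).  The elastic part is
strictly increasing in A; the rate term models wall visco-elasticity.

In reduced mode every vessel collapses to one R-L-C segment with the same
resistance, inertance and compliance integrals and the same elevation gain,
so the full closed-loop tilt protocol runs in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .core import BLOOD, MMHG_PA, FluidProperties

DEFAULT_P_REF_MMHG = 75.0  # diastolic calibration pressure of the tube law


def load_vessel_table(path: str | None = None) -> pd.DataFrame:
    """Load the arterial geometry table (packaged 63-artery default).

    Columns: name, parent ('-' for the root), bed (terminal 0D bed or empty),
    length_cm, r_prox_mm, r_dist_mm, c0_m_s, dz_m (elevation gain along the
    vessel axis for the standing posture, positive toward the head).
    """
    if path is None:
        with resources.files("tiltsim.data").joinpath("arterial_tree_63.csv").open() as f:
            df = pd.read_csv(f)
    else:
        df = pd.read_csv(path)
    df["bed"] = df["bed"].fillna("")
    if (df["length_cm"] <= 0).any() or (df[["r_prox_mm", "r_dist_mm"]] <= 0).any().any():
        raise ValueError("vessel lengths and radii must be positive")
    return df


@dataclass(frozen=True)
class WallParams:
    """Elastic stiffness ``beta`` [Pa m] and visco-elastic coefficient
    ``gamma`` [Pa s m] of the tube law, with the reference pressure [mmHg]."""

    beta: float
    gamma: float = 0.0
    p_ref_mmhg: float = DEFAULT_P_REF_MMHG


def beta_from_c0(c0: float, a0: float, fluid: FluidProperties = BLOOD) -> float:
    """Elastic coefficient giving linearized wave speed c0 at area a0."""
    return 2.0 * fluid.density * c0 ** 2 * np.sqrt(a0)


def wave_speed(a: float | np.ndarray, a0: float, beta: float,
               fluid: FluidProperties = BLOOD) -> float | np.ndarray:
    """Local Moens-Korteweg-type wave speed c = sqrt(beta sqrt(A)/(2 rho A0))."""
    return np.sqrt(beta * np.sqrt(a) / (2.0 * fluid.density * a0))


def tube_law_pressure(a: float, a0: float, da_dt: float, wall: WallParams,
                      p_ext: float = 0.0) -> float:
    """Transmural tube-law pressure [mmHg] at area ``a`` [m^2].

    Elastic term strictly increasing in ``a``; with ``wall.gamma == 0`` the
    law is purely elastic.  Collapsed states (a <= 0) are unsupported in the
    1D arteries.
    """
    if not (a > 0 and a0 > 0):
        raise ValueError(f"cross-section must be positive (a={a}, a0={a0})")
    elastic = wall.beta / a0 * (np.sqrt(a) - np.sqrt(a0))
    visco = wall.gamma / a0 ** 1.5 * da_dt
    return wall.p_ref_mmhg + (elastic + visco) / MMHG_PA + p_ext


@dataclass(frozen=True)
class Vessel1D:
    """One tapered vessel with its numerical grid (SI units)."""

    name: str
    length: float            # m
    r_prox: float            # m
    r_dist: float            # m
    c0: float                # m/s at reference area
    dz: float                # elevation gain prox->dist, standing [m]
    gamma: float = 0.0       # visco-elastic coefficient [Pa s m]
    n_nodes: int = 0         # grid nodes (0 -> from dx target)
    dx_target: float = 2.5e-3

    def __post_init__(self) -> None:
        if self.length <= 0 or self.r_prox <= 0 or self.r_dist <= 0:
            raise ValueError(f"invalid geometry for vessel {self.name}")
        if self.n_nodes == 0:
            object.__setattr__(self, "n_nodes",
                               max(5, int(round(self.length / self.dx_target)) + 1))

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(0.0, self.length, self.n_nodes)

    def radius(self, x: np.ndarray | float) -> np.ndarray | float:
        return self.r_prox + (self.r_dist - self.r_prox) * np.asarray(x) / self.length

    def a0(self, x: np.ndarray | float) -> np.ndarray | float:
        return np.pi * self.radius(x) ** 2

    def beta(self, x: np.ndarray | float, fluid: FluidProperties = BLOOD) -> np.ndarray | float:
        return beta_from_c0(self.c0, self.a0(x), fluid)

    @property
    def char_impedance(self) -> float:
        """Characteristic impedance rho c0 / A0 at the distal end [Pa s m^-3]."""
        a0 = float(self.a0(self.length))
        return BLOOD.density * self.c0 / a0


def vessels_from_table(df: pd.DataFrame, gamma_tau: float = 3.0e-4,
                       dx: float = 2.5e-3) -> dict[str, Vessel1D]:
    """Build Vessel1D objects; gamma = beta * gamma_tau (a wall relaxation
    time of a fraction of a millisecond)."""
    out = {}
    for r in df.itertuples():
        a0m = np.pi * ((r.r_prox_mm + r.r_dist_mm) / 2 * 1e-3) ** 2
        beta = beta_from_c0(r.c0_m_s, a0m)
        out[r.name] = Vessel1D(
            name=r.name, length=r.length_cm * 1e-2,
            r_prox=r.r_prox_mm * 1e-3, r_dist=r.r_dist_mm * 1e-3,
            c0=r.c0_m_s, dz=r.dz_m, gamma=beta * gamma_tau, dx_target=dx)
    return out


@dataclass(frozen=True)
class TerminalCoupling:
    """Characteristic-impedance coupling of a 1D (or reduced) vessel outlet
    to its downstream 0D compartment: Q = (p_end - p_0d)/Zc."""

    vessel: str
    zc: float           # mmHg s / ml
    bed: str

    def __post_init__(self) -> None:
        if not self.zc > 0:
            raise ValueError("Zc must be positive")


def terminal_flux(p_end: float, zc: float, p_0d: float) -> float:
    """Flow [ml/s] through a terminal characteristic impedance [mmHg s/ml]."""
    if not np.isfinite(p_end) or not np.isfinite(p_0d):
        raise ValueError("non-finite terminal pressures")
    return (p_end - p_0d) / zc


# ---------------------------------------------------------------------------
# Reduced-order (0D chain) fallback
# ---------------------------------------------------------------------------

@dataclass
class ReducedTree:
    """Per-vessel R-L-C segments of the reduced arterial tree.

    Units: R in mmHg s/ml, L in mmHg s^2/ml, C in ml/mmHg, dz in m.
    ``parent[i]`` is the index of the upstream vessel (-1 for the root);
    ``bed[i]`` names the terminal 0D bed ('' for internal vessels);
    ``zc[i]`` is the terminal characteristic impedance (0 for internal).
    ``z_mid[i]`` is the elevation of the vessel's distal node relative to the
    heart for the standing posture (sum of dz along the path).
    """

    names: list[str]
    parent: np.ndarray
    R: np.ndarray
    L: np.ndarray
    C: np.ndarray
    dz: np.ndarray
    z_end: np.ndarray
    bed: list[str]
    zc: np.ndarray

    @property
    def n(self) -> int:
        return len(self.names)


def reduce_tree(df: pd.DataFrame, fluid: FluidProperties = BLOOD,
                stiffness_scale: float = 1.0) -> ReducedTree:
    """Collapse each tapered vessel to one R-L-C segment.

    The integrals over the vessel length are preserved:
    R = int 8 mu / (pi r^4) dx,  L = int rho/A dx,  C = int A0/(rho c0^2) dx,
    converted to the mmHg/ml/s system.  ``stiffness_scale`` multiplies every
    beta (and hence divides every compliance) for global wall-stiffness
    calibration.
    """
    names = list(df["name"])
    idx = {n: i for i, n in enumerate(names)}
    n = len(names)
    parent = np.full(n, -1, dtype=np.int64)
    R = np.zeros(n); L = np.zeros(n); C = np.zeros(n)
    dz = np.zeros(n); zc = np.zeros(n)
    bed = [""] * n
    mu = fluid.viscosity
    rho = fluid.density
    for i, r in enumerate(df.itertuples()):
        length = r.length_cm * 1e-2
        rp, rd = r.r_prox_mm * 1e-3, r.r_dist_mm * 1e-3
        x = np.linspace(0, 1, 21)
        rad = rp + (rd - rp) * x
        a = np.pi * rad ** 2
        R_si = np.trapezoid(8 * mu / (np.pi * rad ** 4), x) * length
        L_si = np.trapezoid(rho / a, x) * length
        c0 = r.c0_m_s
        C_si = np.trapezoid(a / (rho * c0 ** 2), x) * length / stiffness_scale
        # SI (Pa s/m^3 etc.) -> mmHg / ml / s
        R[i] = R_si / MMHG_PA * 1e-6
        L[i] = L_si / MMHG_PA * 1e-6
        C[i] = C_si * MMHG_PA * 1e6
        dz[i] = r.dz_m
        parent[i] = idx[r.parent] if r.parent != "-" else -1
        if r.bed:
            bed[i] = r.bed
            a0d = np.pi * rd ** 2
            zc[i] = rho * c0 / a0d / MMHG_PA * 1e-6
    z_end = np.zeros(n)
    for i in range(n):
        z_end[i] = dz[i] + (z_end[parent[i]] if parent[i] >= 0 else 0.0)
    return ReducedTree(names=names, parent=parent, R=R, L=L, C=C, dz=dz,
                       z_end=z_end, bed=bed, zc=zc)
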