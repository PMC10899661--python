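"""Explicit 1D pulse-wave solver for the arterial tree.

Cross-sectionally averaged mass/momentum balance on (A, Q) per vessel:

    dA/dt + dQ/dx = 0
    dQ/dt + d(Q^2/A)/dx + (A/rho) dp/dx = -k_f pi nu Q/A + g_x A

with the elastic tube law p = p_d + beta/A0 (sqrt(A) - sqrt(A0)) and an
operator-split visco-elastic correction (diffusive term on Q).  The scheme
is MacCormack predictor-corrector (second order); boundaries use the
Riemann invariants W_{1,2} = u +/- 4c of the tube law; junctions enforce
mass conservation and total-pressure continuity via Newton iteration;
terminals couple through characteristic impedances to 0D pressures.

Everything in this module is SI (m, s, Pa); the coupling layer converts to
the physiological units of the 0D network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import BLOOD, MMHG_PA
from .arterial import Vessel1D, beta_from_c0

RHO = BLOOD.density
NU = BLOOD.viscosity / BLOOD.density
K_FRICTION = 8.0          # Poiseuille profile; configurable friction factor


@dataclass
class VesselGrid:
    """Discretized vessel state."""
    name: str
    x: np.ndarray
    a0: np.ndarray
    beta: np.ndarray
    gamma: float
    dzdx: float              # elevation gain per unit length (standing)
    a: np.ndarray = field(default=None)
    q: np.ndarray = field(default=None)
    p_d: float = 75.0 * MMHG_PA   # tube-law reference pressure [Pa]

    def __post_init__(self):
        if self.a is None:
            self.a = self.a0.copy()
        if self.q is None:
            self.q = np.zeros_like(self.a0)

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])

    def pressure(self) -> np.ndarray:
        return self.p_d + self.beta / self.a0 * (np.sqrt(self.a) - np.sqrt(self.a0))

    def wave_speed(self) -> np.ndarray:
        return np.sqrt(self.beta * np.sqrt(self.a) / (2.0 * RHO * self.a0))


def make_grid(v: Vessel1D, dx: float | None = None) -> VesselGrid:
    n = v.n_nodes if dx is None else max(5, int(round(v.length / dx)) + 1)
    x = np.linspace(0.0, v.length, n)
    a0 = np.asarray(v.a0(x), dtype=float)
    beta = np.asarray(v.beta(x), dtype=float)
    return VesselGrid(name=v.name, x=x, a0=a0, beta=beta, gamma=v.gamma,
                      dzdx=v.dz / v.length)


def _pressure(a, a0, beta, p_d):
    return p_d + beta / a0 * (np.sqrt(a) - np.sqrt(a0))


def _celerity(a, a0, beta):
    return np.sqrt(beta * np.sqrt(a) / (2.0 * RHO * a0))


def max_dt(grids: list[VesselGrid], cfl: float = 0.9) -> float:
    """Largest stable step from the CFL condition (and the visco-elastic
    diffusion limit where active)."""
    dt = np.inf
    for g in grids:
        c = g.wave_speed()
        u = np.abs(g.q / g.a)
        lim = cfl * g.dx / np.max(u + c)
        if g.gamma > 0:
            d = g.gamma / (RHO * np.sqrt(np.max(g.a0)))
            lim = min(lim, 0.45 * g.dx ** 2 / d)
        dt = min(dt, lim)
    return float(dt)


def check_cfl(g: VesselGrid, dt: float, cfl: float = 0.9) -> None:
    c = g.wave_speed()
    u = np.abs(g.q / g.a)
    lim = cfl * g.dx / np.max(u + c)
    if dt > lim:
        raise ValueError(
            f"CFL violation in vessel {g.name!r}: dt={dt:.3e} exceeds "
            f"{lim:.3e}; reduce dt to at most {lim:.3e}")


def advance_vessel(g: VesselGrid, dt: float, sin_a: float = 0.0,
                   check: bool = True,
                   return_fluxes: bool = False) -> tuple[float, float] | None:
    """One MacCormack step of the interior nodes (boundaries untouched).

    Gravity enters as the axial projection g sin(alpha) dz/dx; friction is
    the configured Poiseuille-profile term.  A zero-flow uniform-pressure
    state with no forcing and alpha = 0 is an exact equilibrium.

    With ``return_fluxes`` the scheme's effective boundary mass fluxes
    (F_left, F_right) of the interior control volume are returned: the
    interior volume change equals -dt (F_right - F_left) to round-off,
    which is the per-step mass-defect audit.
    """
    if np.any(g.a <= 0):
        raise ValueError(f"collapsed cross-section in vessel {g.name!r}")
    if check:
        check_cfl(g, dt)
    a, q = g.a, g.q
    dx = g.dx
    gx = -9.81 * g.dzdx * sin_a

    def rhs_terms(a_, q_):
        p = _pressure(a_, g.a0, g.beta, g.p_d)
        fa = q_
        fq = q_ * q_ / a_
        src = -K_FRICTION * np.pi * NU * q_ / a_ + gx * a_
        return p, fa, fq, src

    p, fa, fq, src = rhs_terms(a, q)
    # predictor (forward differences)
    ap = a.copy(); qp = q.copy()
    ap[:-1] = a[:-1] - dt / dx * (fa[1:] - fa[:-1])
    qp[:-1] = q[:-1] - dt / dx * (fq[1:] - fq[:-1]) \
        - dt / dx * a[:-1] / RHO * (p[1:] - p[:-1]) + dt * src[:-1]
    pp, fap, fqp, srcp = rhs_terms(ap, qp)
    # corrector (backward differences)
    an = a.copy(); qn = q.copy()
    an[1:-1] = 0.5 * (a[1:-1] + ap[1:-1] - dt / dx * (fap[1:-1] - fap[:-2]))
    qn[1:-1] = 0.5 * (q[1:-1] + qp[1:-1]
                      - dt / dx * (fqp[1:-1] - fqp[:-2])
                      - dt / dx * ap[1:-1] / RHO * (pp[1:-1] - pp[:-2])
                      + dt * srcp[1:-1])
    # visco-elastic correction: diffusion on Q (operator split)
    if g.gamma > 0:
        d = g.gamma / (RHO * np.sqrt(g.a0[1:-1]))
        qn[1:-1] += dt * d * (qn[2:] - 2 * qn[1:-1] + qn[:-2]) / dx ** 2
    g.a, g.q = an, qn
    if return_fluxes:
        f_left = 0.5 * (fa[1] + qp[0])
        f_right = 0.5 * (fa[-1] + qp[-2])
        return f_left, f_right
    return None


def _w_forward(g: VesselGrid, i: int) -> float:
    """Outgoing characteristic W1 = u + 4c at interior node near the distal
    end (extrapolated to the boundary)."""
    u = g.q[i] / g.a[i]
    return u + 4.0 * _celerity(g.a[i], g.a0[i], g.beta[i])


def _w_backward(g: VesselGrid, i: int) -> float:
    u = g.q[i] / g.a[i]
    return u - 4.0 * _celerity(g.a[i], g.a0[i], g.beta[i])


def apply_inlet_flow(g: VesselGrid, q_in: float) -> None:
    """Prescribed-flow inlet: solve A from the outgoing (backward)
    characteristic of the interior."""
    w2 = _w_backward(g, 1)
    a = g.a[0]
    for _ in range(30):
        c = _celerity(a, g.a0[0], g.beta[0])
        f = q_in / a - 4.0 * c - w2
        dfda = -q_in / a ** 2 - 4.0 * 0.25 * c / a
        step = f / dfda
        a_new = a - step
        if a_new <= 0:
            a_new = 0.5 * a
        if abs(a_new - a) < 1e-16:
            a = a_new
            break
        a = a_new
    g.a[0] = a
    g.q[0] = q_in


def apply_inlet_pressure(g: VesselGrid, p_in: float) -> None:
    """Prescribed-pressure inlet (Pa): invert the tube law for A, take Q
    from the outgoing characteristic."""
    s = (p_in - g.p_d) * g.a0[0] / g.beta[0] + np.sqrt(g.a0[0])
    a = s * s
    w2 = _w_backward(g, 1)
    u = w2 + 4.0 * _celerity(a, g.a0[0], g.beta[0])
    g.a[0] = a
    g.q[0] = a * u


def apply_terminal(g: VesselGrid, zc_si: float, p_out: float) -> float:
    """Characteristic-impedance outlet: Q = (p - p_out)/Zc combined with
    the outgoing W1; returns the terminal flow [m^3/s]."""
    w1 = _w_forward(g, -2)
    n = len(g.a) - 1
    a = g.a[n]
    for _ in range(40):
        c = _celerity(a, g.a0[n], g.beta[n])
        p = _pressure(a, g.a0[n], g.beta[n], g.p_d)
        f = a * (w1 - 4.0 * c) - (p - p_out) / zc_si
        dcda = 0.25 * c / a
        dpda = g.beta[n] / (2.0 * g.a0[n] * np.sqrt(a))
        dfda = (w1 - 4.0 * c) - 4.0 * a * dcda - dpda / zc_si
        a_new = a - f / dfda
        if a_new <= 0:
            a_new = 0.5 * a
        if abs(a_new - a) < 1e-16:
            a = a_new
            break
        a = a_new
    g.a[n] = a
    g.q[n] = a * (w1 - 4.0 * _celerity(a, g.a0[n], g.beta[n]))
    return float(g.q[n])


def solve_junction(parent: VesselGrid, daughters: list[VesselGrid],
                   max_iter: int = 50, tol: float = 1e-11) -> None:
    """Couple a parent outlet to 1-2 daughter inlets.

    Enforces mass conservation and continuity of total pressure
    p + rho u^2 / 2, with the outgoing characteristics of each vessel
    preserved.  Newton iteration on the end areas; raises on
    non-convergence with a residual report.
    """
    np_end = len(parent.a) - 1
    w1 = _w_forward(parent, -2)
    w2s = [_w_backward(d, 1) for d in daughters]
    nd = len(daughters)

    def unpack(z):
        ap = z[0]
        ads = z[1:1 + nd]
        return ap, ads

    def resid(z):
        ap, ads = unpack(z)
        cp = _celerity(ap, parent.a0[np_end], parent.beta[np_end])
        up = w1 - 4.0 * cp
        pp = _pressure(ap, parent.a0[np_end], parent.beta[np_end], parent.p_d)
        r = np.zeros(1 + nd)
        q_out = 0.0
        for k, (d, w2) in enumerate(zip(daughters, w2s)):
            cd = _celerity(ads[k], d.a0[0], d.beta[0])
            ud = w2 + 4.0 * cd
            pd_ = _pressure(ads[k], d.a0[0], d.beta[0], d.p_d)
            r[1 + k] = (pp + 0.5 * RHO * up ** 2) - (pd_ + 0.5 * RHO * ud ** 2)
            q_out += ads[k] * ud
        r[0] = ap * up - q_out
        return r

    z = np.array([parent.a[np_end]] + [d.a[0] for d in daughters])
    scale = max(parent.beta[np_end] / parent.a0[np_end] * np.sqrt(parent.a0[np_end]), 1.0)
    for it in range(max_iter):
        r = resid(z)
        if np.max(np.abs(r / np.array([z[0] * 1.0] + [scale] * nd))) < tol:
            break
        jac = np.zeros((1 + nd, 1 + nd))
        for j in range(1 + nd):
            dz = z[j] * 1e-8
            zp = z.copy(); zp[j] += dz
            jac[:, j] = (resid(zp) - r) / dz
        try:
            step = np.linalg.solve(jac, r)
        except np.linalg.LinAlgError as e:
            raise RuntimeError(f"junction Newton singular at {parent.name}: {e}")
        z = z - step
        z = np.maximum(z, 1e-10)
    else:
        raise RuntimeError(
            f"junction at {parent.name!r} did not converge in {max_iter} "
            f"iterations; residual {resid(z)}")
    ap, ads = unpack(z)
    cp = _celerity(ap, parent.a0[np_end], parent.beta[np_end])
    parent.a[np_end] = ap
    parent.q[np_end] = ap * (w1 - 4.0 * cp)
    for k, (d, w2) in enumerate(zip(daughters, w2s)):
        cd = _celerity(ads[k], d.a0[0], d.beta[0])
        d.a[0] = ads[k]
        d.q[0] = ads[k] * (w2 + 4.0 * cd)


@dataclass
class Network1D:
    """A tree of vessel grids with junction topology and terminal loads."""
    grids: dict[str, VesselGrid]
    children: dict[str, list[str]]
    root: str
    terminals: dict[str, tuple[float, float]]   # name -> (Zc SI, p_out Pa)

    def step(self, dt: float, q_in: float | None = None,
             p_in: float | None = None, sin_a: float = 0.0,
             check: bool = False) -> dict[str, float]:
        """Advance the whole network one step; returns terminal flows."""
        for g in self.grids.values():
            advance_vessel(g, dt, sin_a=sin_a, check=check)
        if q_in is not None:
            apply_inlet_flow(self.grids[self.root], q_in)
        elif p_in is not None:
            apply_inlet_pressure(self.grids[self.root], p_in)
        flows = {}
        for name, g in self.grids.items():
            kids = self.children.get(name, [])
            if kids:
                solve_junction(g, [self.grids[k] for k in kids])
            else:
                zc, p_out = self.terminals[name]
                flows[name] = apply_terminal(g, zc, p_out)
        return flows

    def total_volume(self) -> float:
        return float(sum(np.trapezoid(g.a, g.x) for g in self.grids.values()))


def build_network(df, names: list[str] | None = None, dx: float = 2.5e-3,
                  gamma_tau: float = 0.0,
                  terminal_loads: dict[str, tuple[float, float]] | None = None
                  ) -> Network1D:
    """Assemble a Network1D from (a subset of) the vessel table.

    ``terminal_loads`` maps leaf vessel names to (Zc [mmHg s/ml], p_out
    [mmHg]); leaves without an entry get their own characteristic impedance
    (non-reflecting) against p_out = tube-law reference pressure.
    """
    from .arterial import vessels_from_table
    vessels = vessels_from_table(df, gamma_tau=gamma_tau, dx=dx)
    if names is None:
        names = list(df["name"])
    sub = {n: vessels[n] for n in names}
    parent_of = {r.name: r.parent for r in df.itertuples() if r.name in sub}
    children: dict[str, list[str]] = {}
    root = None
    for n in names:
        p = parent_of[n]
        if p == "-" or p not in sub:
            root = n
        else:
            children.setdefault(p, []).append(n)
    grids = {n: make_grid(v, dx=dx) for n, v in sub.items()}
    terminals = {}
    for n in names:
        if n not in children or not children[n]:
            if terminal_loads and n in terminal_loads:
                zc_mmhg, p_mmhg = terminal_loads[n]
                terminals[n] = (zc_mmhg * MMHG_PA * 1e6, p_mmhg * MMHG_PA)
            else:
                g = grids[n]
                zc = RHO * float(_celerity(g.a0[-1], g.a0[-1], g.beta[-1])) / g.a0[-1]
                terminals[n] = (zc, g.p_d)
    return Network1D(grids=grids, children=children, root=root,
                     terminals=terminals)
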