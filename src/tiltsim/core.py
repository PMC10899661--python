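"""Units, body geometry, gravity/posture kinematics and the tilt protocol.

Shared vocabulary for the whole simulator:

* the tilt angle ``alpha`` is measured in degrees from the horizontal;
  +80 deg is 80 deg head-up tilt (HUT), -6 deg is 6 deg head-down tilt (HDT);
* the hydrostatic reference (zero elevation) is the aortic root / heart level;
  axial site positions are metres along the longitudinal body axis, positive
  toward the head;
* pressures cross the module boundary in mmHg, volumes in ml, times in s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MMHG_PA = 133.322  # 1 mmHg in Pa
G_EARTH = 9.81     # m s^-2

BLOOD_DENSITY = 1050.0   # kg m^-3
CSF_DENSITY = 1000.0     # kg m^-3
BLOOD_VISCOSITY = 4.0e-3  # Pa s


def mmhg_to_pa(p: float | np.ndarray) -> float | np.ndarray:
    return np.multiply(p, MMHG_PA)


def pa_to_mmhg(p: float | np.ndarray) -> float | np.ndarray:
    return np.divide(p, MMHG_PA)


@dataclass(frozen=True)
class FluidProperties:
    """Density [kg/m^3] and dynamic viscosity [Pa s] of a working fluid."""

    density: float = BLOOD_DENSITY
    viscosity: float = BLOOD_VISCOSITY

    def __post_init__(self) -> None:
        if not (self.density > 0 and self.viscosity > 0):
            raise ValueError("fluid density and viscosity must be positive")


BLOOD = FluidProperties(BLOOD_DENSITY, BLOOD_VISCOSITY)
CSF = FluidProperties(CSF_DENSITY, 0.8e-3)


@dataclass(frozen=True)
class BodyGeometry:
    """Axial site elevations [m] relative to the heart (aortic root).

    ``axial_position`` maps a named site to its distance along the
    longitudinal body axis (positive toward the head).  These are *effective*
    lumped elevations calibrated so that the hydrostatic columns reproduce
    physiological posture responses; they are not anatomical lengths.
    ``eye_anterior_offset`` is the perpendicular distance of the globe
    anterior to the mid-coronal plane: it makes eye-level pressures dip when
    the body is near horizontal (cos term) rather than upright (sin term).
    """

    axial_position: dict[str, float] = field(default_factory=lambda: dict(
        heart=0.0,
        carotid_sinus=0.22,
        head=0.345,          # intracranial nodes, ICA terminus level
        eye=0.3452,
        svc=0.035,           # effective centroid of the superior vena cava
        dvs=0.17,            # dural venous sinus = svc + svc_head_distance
        csf_neutral=0.2215,  # hydrostatic indifferent point of the CSF space
    ))
    eye_anterior_offset: float = 0.0286
    svc_head_distance: float = 0.135

    def __post_init__(self) -> None:
        if not self.svc_head_distance > 0:
            raise ValueError("svc_head_distance must be positive")
        if not self.eye_anterior_offset > 0:
            raise ValueError("eye_anterior_offset must be positive")
        for k, v in self.axial_position.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite axial position for site {k!r}")


@dataclass(frozen=True)
class TiltProtocol:
    """Piecewise tilt-table trajectory: dwell segments joined by linear ramps.

    ``segments`` is a list of ``(angle_deg, dwell_s)`` pairs.  The table sits
    at the first segment's angle for its dwell, then ramps linearly over
    ``ramp_duration`` seconds to the next angle, and so on.  Times before
    ``t0`` report the first segment's angle.
    """

    segments: tuple[tuple[float, float], ...] = ((80.0, 300.0), (-6.0, 600.0), (80.0, 900.0))
    ramp_duration: float = 15.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        if len(self.segments) == 0:
            raise ValueError("protocol needs at least one segment")
        if not self.ramp_duration > 0:
            raise ValueError("ramp_duration must be positive")
        for angle, dwell in self.segments:
            if not -90.0 <= angle <= 90.0:
                raise ValueError(f"tilt angle {angle} outside [-90, 90] deg")
            if dwell < 0:
                raise ValueError("dwell must be non-negative")

    @property
    def duration(self) -> float:
        """Total protocol duration from t0 (dwells plus ramps) in seconds."""
        return float(sum(d for _, d in self.segments)
                     + self.ramp_duration * (len(self.segments) - 1))

    def knots(self) -> tuple[np.ndarray, np.ndarray]:
        """Time/angle breakpoints of the piecewise-linear trajectory."""
        ts, angs = [self.t0], [self.segments[0][0]]
        t = self.t0
        for i, (angle, dwell) in enumerate(self.segments):
            t += dwell
            ts.append(t)
            angs.append(angle)
            if i + 1 < len(self.segments):
                t += self.ramp_duration
                ts.append(t)
                angs.append(self.segments[i + 1][0])
        return np.asarray(ts), np.asarray(angs)

    def window(self, index: int) -> tuple[float, float]:
        """(start, end) time of dwell segment ``index`` (ramps excluded)."""
        t = self.t0
        for i, (_, dwell) in enumerate(self.segments):
            if i == index:
                return (t, t + dwell)
            t += dwell + self.ramp_duration
        raise IndexError(index)


def tilt_angle_at(t: float | np.ndarray, protocol: TiltProtocol) -> float | np.ndarray:
    """Instantaneous tilt angle [deg]: constant in dwells, linear in ramps.

    Continuous everywhere; times before ``protocol.t0`` return the first
    segment's angle (the table is parked), times beyond the end return the
    last segment's angle.
    """
    ts, angs = protocol.knots()
    out = np.interp(np.asarray(t, dtype=float), ts, angs)
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(out)
    return out


def hydrostatic_delta_p(axial_dist: float, perp_dist: float, angle: float,
                        fluid: FluidProperties = BLOOD) -> float:
    """Hydrostatic pressure head [mmHg] of a tilted fluid column.

    ``rho * g * (axial_dist * sin(angle) + perp_dist * cos(angle))`` converted
    to mmHg.  Positive when the site sits above the reference: the local
    pressure at the site is then ``p_reference - delta_p``.
    """
    vals = (axial_dist, perp_dist, angle)
    if not all(np.isfinite(v) for v in vals):
        raise ValueError(f"non-finite input to hydrostatic_delta_p: {vals}")
    a = np.deg2rad(angle)
    dp_pa = fluid.density * G_EARTH * (axial_dist * np.sin(a) + perp_dist * np.cos(a))
    return float(dp_pa / MMHG_PA)


def hydro_coeff(fluid: FluidProperties = BLOOD) -> float:
    """rho*g per metre of column, in mmHg/m (77.3 for blood)."""
    return fluid.density * G_EARTH / MMHG_PA
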