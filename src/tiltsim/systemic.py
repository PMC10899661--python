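"""Lumped systemic building blocks: time-varying elastance chambers, valve
law, posture-dependent intrathoracic pressure, and compartment helpers.

These are the canonical (documented, unit-tested) forms of the laws that the
compiled closed-loop right-hand side in :mod:`tiltsim.model` inlines for
speed; the activation waveform is shared outright.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import _activation
from .params import HeartParams, ItpParams


@dataclass
class CardiacChamber:
    """Elastance chamber: Emin/Emax [mmHg/ml], unstressed volume V0 [ml]."""
    e_min: float
    e_max: float
    v0: float
    volume: float = 120.0

    def __post_init__(self) -> None:
        if not (self.e_max >= self.e_min > 0):
            raise ValueError("need Emax >= Emin > 0")
        if self.volume <= 0:
            raise ValueError("chamber volume must be positive")


def chamber_elastance(t_in_beat: float, chamber: CardiacChamber,
                      heart_period: float,
                      heart: HeartParams | None = None,
                      atrial: bool = False) -> float:
    """Instantaneous elastance [mmHg/ml] at phase ``t_in_beat`` of the beat.

    Smooth and periodic; equals Emin in diastole and reaches Emax at the
    activation peak.
    """
    if not 0.0 <= t_in_beat < heart_period:
        raise ValueError("t_in_beat must lie within [0, heart_period)")
    h = heart or HeartParams()
    ev, ea = _activation(t_in_beat, heart_period, h.tvc_scale, h.tvr_scale,
                         h.tac_scale, h.tac_base, h.av_delay)
    act = ea if atrial else ev
    return chamber.e_min + (chamber.e_max - chamber.e_min) * act


def valve_flow(p_up: float, p_down: float, resistance: float,
               bernoulli: float = 0.0) -> float:
    """Unidirectional valve flow [ml/s]: zero for any non-positive gradient.

    Forward law: linear resistance, optionally with a Bernoulli (quadratic)
    term ``dp = R q + b q^2``.
    """
    if not (np.isfinite(p_up) and np.isfinite(p_down)):
        raise ValueError("non-finite valve pressures")
    dp = p_up - p_down
    if dp <= 0.0:
        return 0.0
    if bernoulli > 0.0:
        return (-resistance + np.sqrt(resistance ** 2 + 4 * bernoulli * dp)) / (2 * bernoulli)
    return dp / resistance


def itp_at(angle: float, model: ItpParams) -> float:
    """Intrathoracic pressure [mmHg] at tilt angle [deg].

    Linear in sin(angle): supine value at 0 deg, upright value at +90 deg,
    continuous everywhere (head-down angles extrapolate the same law).
    """
    if not -90.0 <= angle <= 90.0:
        raise ValueError("angle outside [-90, 90]")
    return model.supine + (model.upright - model.supine) * np.sin(np.deg2rad(angle))


def rc_step_response(p0: float, p_inf: float, tau: float, t: float | np.ndarray):
    """Closed-form relaxation of a single R-C compartment (test oracle)."""
    return p_inf + (p0 - p_inf) * np.exp(-np.asarray(t) / tau)
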