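"""Conversions between kinematic coefficient triples and (sensitivity, phase) phasors.

A neuron's modulation to a sinusoidal rotation at frequency ``f`` is summarized
by a phasor: sensitivity (gain re angular velocity, (sp/s)/(°/s)) and phase
(lead re velocity, degrees). For a coefficient triple (c_p, c_v, c_a) acting on
position/velocity/acceleration of the same channel,

    sensitivity = sqrt(((2*pi*f)**2 * c_a - c_p)**2 + (2*pi*f*c_v)**2) / (2*pi*f)
    phase       = atan2((2*pi*f)**2 * c_a - c_p, 2*pi*f*c_v)

The quadrant-aware atan2 keeps anti-phase responses (|phase| > 90°, i.e. a
sign-flipped coefficient branch) representable.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "coeffs_to_sensitivity_phase",
    "sensitivity_phase_to_coeffs",
    "wrap_phase_deg",
    "branch_sign",
]


def wrap_phase_deg(phase: float) -> float:
    """Wrap a phase in degrees to the interval (-180, 180]."""
    wrapped = math.fmod(phase + 180.0, 360.0)
    if wrapped <= 0.0:
        wrapped += 360.0
    return wrapped - 180.0


def coeffs_to_sensitivity_phase(
    c_p: float, c_v: float, c_a: float, freq: float = 1.0
) -> tuple[float, float]:
    """Return (sensitivity, phase_deg) of a coefficient triple at ``freq`` Hz.

    Sensitivity is non-negative (gain re angular velocity); phase is in
    (-180, 180] and absorbs the sign branch: an all-non-positive triple maps to
    |phase| > 90.
    """
    omega = 2.0 * math.pi * freq
    q = omega**2 * c_a - c_p
    sens = math.hypot(q, omega * c_v) / omega
    if sens == 0.0:
        return 0.0, 0.0
    phase = math.degrees(math.atan2(q, omega * c_v))
    return sens, wrap_phase_deg(phase)


def sensitivity_phase_to_coeffs(
    sensitivity: float, phase_deg: float, freq: float = 1.0
) -> tuple[float, float, float]:
    """Invert a (sensitivity, phase) phasor into a sign-consistent triple.

    Any triple realizing the phasor at ``freq`` is acceptable; this inversion
    puts the quadrature component into position *or* acceleration, whichever
    keeps all coefficients on one sign branch:

    - phase in [0, 90]:    (0, +c_v, +c_a)
    - phase in [-90, 0]:   (+c_p, +c_v, 0)
    - phase in (90, 180]:  (-c_p, -c_v, 0)
    - phase in (-180,-90): (0, -c_v, -c_a)

    Round-trips exactly through :func:`coeffs_to_sensitivity_phase`.
    """
    if sensitivity < 0:
        raise ValueError("sensitivity must be non-negative")
    omega = 2.0 * math.pi * freq
    phi = math.radians(wrap_phase_deg(phase_deg))
    c_v = sensitivity * math.cos(phi)
    q = omega * sensitivity * math.sin(phi)  # = omega**2 * c_a - c_p
    if c_v >= 0.0:
        if q >= 0.0:
            return 0.0, c_v, q / omega**2
        return -q, c_v, 0.0
    if q <= 0.0:
        return 0.0, c_v, q / omega**2
    return -q, c_v, 0.0


def branch_sign(c_p: float, c_v: float, c_a: float) -> int:
    """Sign branch of a sign-consistent triple: +1, -1, or 0 if all zero."""
    coeffs = np.asarray([c_p, c_v, c_a], dtype=float)
    if np.all(coeffs == 0.0):
        return 0
    if np.all(coeffs >= 0.0):
        return 1
    if np.all(coeffs <= 0.0):
        return -1
    raise ValueError("coefficients do not share one sign")
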