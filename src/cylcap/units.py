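"""Unit conventions: SI internally, ecological units at the interface.

Field measurements in this problem are reported in cm/s (velocities) and
micrometres (collector and particle diameters); all internal computation is
in SI (m, s, particles/m^3).  The two helpers here convert once at the
boundary, so conversion round-trips are exact to float precision.
"""

from __future__ import annotations

__all__ = [
    "CM_PER_S",
    "MICRON",
    "WATER_KINEMATIC_VISCOSITY",
    "eco_to_si",
    "si_to_eco",
]

CM_PER_S = 1e-2  # m/s per cm/s
MICRON = 1e-6  # m per micrometre

#: Kinematic viscosity of water near 20 C [m^2/s]; the default working fluid.
WATER_KINEMATIC_VISCOSITY = 1e-6


def eco_to_si(*, velocity_cm_s: float | None = None, length_um: float | None = None):
    """Convert ecological-convention values to SI.

    Returns the converted velocity [m/s], length [m], or a tuple of those
    provided (velocity first).
    """
    out = []
    if velocity_cm_s is not None:
        out.append(velocity_cm_s * CM_PER_S)
    if length_um is not None:
        out.append(length_um * MICRON)
    if not out:
        raise ValueError("nothing to convert")
    return tuple(out) if len(out) > 1 else out[0]


def si_to_eco(*, velocity_m_s: float | None = None, length_m: float | None = None):
    """Inverse of :func:`eco_to_si`."""
    out = []
    if velocity_m_s is not None:
        out.append(velocity_m_s / CM_PER_S)
    if length_m is not None:
        out.append(length_m / MICRON)
    if not out:
        raise ValueError("nothing to convert")
    return tuple(out) if len(out) > 1 else out[0]
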