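"""Dimensional contact-rate prediction and biomass-division analysis.

The approaching particle flux through a cylindrical collector's upstream
window is F_p = C_p * U_inf * h_c * D_c; the contact rate is CR = eta * F_p
with eta the contact efficiency at the collector's (Re, r_p).  Under a local
power law eta = k2 Re^alpha r_p^beta this expands to

    CR = k2 C_p h_c nu^(-alpha) U_inf^(1+alpha) D_p^beta D_c^(1+alpha-beta),

which makes the roles of the dimensional drivers explicit (gamma = 1+alpha
on velocity, delta = 1+alpha-beta on collector diameter).

``biomass_division`` quantifies the advantage of splitting a fixed collector
biomass (constant total cross-sectional area at fixed height) among n
thinner cylinders, each of diameter D_c/sqrt(n): on a power-law patch the
total-rate gain is n^(1 - delta/2).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import pandas as pd

from .models import DimensionlessState, PowerLawModel, power_law_eta
from .surface import EfficiencySurface
from .units import CM_PER_S, MICRON, WATER_KINEMATIC_VISCOSITY

__all__ = [
    "CaptureScenario",
    "ContactPrediction",
    "BiomassDivisionResult",
    "approaching_flux",
    "predict_contact",
    "power_law_CR",
    "biomass_division",
    "calibrate_height",
]


@dataclass(frozen=True)
class CaptureScenario:
    """Dimensional description of one collector in one flow (SI units).

    velocity [m/s], collector_diameter [m], particle_diameter [m],
    collector_height [m], particle_concentration [particles/m^3],
    kinematic_viscosity [m^2/s].
    """

    velocity: float
    collector_diameter: float
    particle_diameter: float
    collector_height: float
    particle_concentration: float
    kinematic_viscosity: float = WATER_KINEMATIC_VISCOSITY

    def __post_init__(self) -> None:
        for name in (
            "velocity",
            "collector_diameter",
            "particle_diameter",
            "collector_height",
            "particle_concentration",
            "kinematic_viscosity",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @classmethod
    def from_eco(
        cls,
        velocity_cm_s: float,
        collector_diameter_um: float,
        particle_diameter_um: float,
        collector_height_m: float,
        particle_concentration_per_m3: float,
        kinematic_viscosity: float = WATER_KINEMATIC_VISCOSITY,
    ) -> "CaptureScenario":
        """Build from ecological units (cm/s, micrometres)."""
        return cls(
            velocity=velocity_cm_s * CM_PER_S,
            collector_diameter=collector_diameter_um * MICRON,
            particle_diameter=particle_diameter_um * MICRON,
            collector_height=collector_height_m,
            particle_concentration=particle_concentration_per_m3,
            kinematic_viscosity=kinematic_viscosity,
        )

    @property
    def state(self) -> DimensionlessState:
        return DimensionlessState.from_dimensional(
            self.velocity,
            self.collector_diameter,
            self.particle_diameter,
            self.kinematic_viscosity,
        )

    @property
    def reynolds(self) -> float:
        return self.state.reynolds

    @property
    def size_ratio(self) -> float:
        return self.state.size_ratio


@dataclass(frozen=True)
class ContactPrediction:
    """A contact-rate prediction with its provenance; CR = eta * F_p exactly."""

    approaching_flux: float  # particles/s
    efficiency: float
    contact_rate: float  # particles/s
    provenance: str
    reynolds: float
    size_ratio: float

    def to_record(self) -> dict:
        return {
            "F_p": self.approaching_flux,
            "eta": self.efficiency,
            "CR": self.contact_rate,
            "provenance": self.provenance,
            "Re": self.reynolds,
            "r_p": self.size_ratio,
            "units": {"F_p": "particles/s", "CR": "particles/s"},
        }

    def to_json(self) -> str:
        return json.dumps(self.to_record())


def approaching_flux(scenario: CaptureScenario) -> float:
    """F_p = C_p * U_inf * h_c * D_c [particles/s]."""
    return (
        scenario.particle_concentration
        * scenario.velocity
        * scenario.collector_height
        * scenario.collector_diameter
    )


def predict_contact(
    scenario: CaptureScenario, surface: EfficiencySurface
) -> ContactPrediction:
    """Predict the contact rate by efficiency lookup on a surface.

    eta is interpolated log-log-bilinearly; (Re, r_p) outside the surface
    raises a coverage error naming the exceeded bound.
    """
    st = scenario.state
    eta = surface.eta_at(st.reynolds, st.size_ratio)
    fp = approaching_flux(scenario)
    return ContactPrediction(
        approaching_flux=fp,
        efficiency=eta,
        contact_rate=eta * fp,
        provenance=surface.source_at(st.reynolds, st.size_ratio),
        reynolds=st.reynolds,
        size_ratio=st.size_ratio,
    )


def power_law_CR(model: PowerLawModel, scenario: CaptureScenario) -> float:
    """Contact rate from the expanded dimensional power law.

    CR = k2 C_p h_c nu^(-alpha) U^(1+alpha) D_p^beta D_c^(1+alpha-beta).
    Equals eta(Re, r_p) * F_p to machine precision by construction.
    """
    a, b = model.alpha_exponent, model.beta_exponent
    return (
        model.coefficient
        * scenario.particle_concentration
        * scenario.collector_height
        * scenario.kinematic_viscosity ** (-a)
        * scenario.velocity ** (1.0 + a)
        * scenario.particle_diameter**b
        * scenario.collector_diameter ** (1.0 + a - b)
    )


@dataclass(frozen=True)
class BiomassDivisionResult:
    """Total and per-collector contact-rate gains from biomass division."""

    n_collectors: int
    divided_diameter: float
    total_ratio: float  # n * CR(D/sqrt(n)) / CR(D)
    per_collector_ratio: float  # CR(D/sqrt(n)) / CR(D)


def biomass_division(
    scenario: CaptureScenario, n_collectors: int, surface: EfficiencySurface
) -> BiomassDivisionResult:
    """Split one collector into n of equal height and the same total biomass.

    Constant biomass at fixed height means constant total cross-sectional
    area, so each of the n cylinders has diameter D_c / sqrt(n).  Returns
    the total contact rate of the group relative to the single original
    collector, and the (minor) per-collector gain.
    """
    if n_collectors < 1:
        raise ValueError("n_collectors must be >= 1")
    base = predict_contact(scenario, surface)
    d_div = scenario.collector_diameter / math.sqrt(n_collectors)
    divided = replace(scenario, collector_diameter=d_div)
    try:
        each = predict_contact(divided, surface)
    except ValueError as exc:
        raise ValueError(
            f"divided collector diameter {d_div:g} m pushes (Re, r_p) outside "
            f"surface coverage: {exc}"
        ) from exc
    per = each.contact_rate / base.contact_rate
    return BiomassDivisionResult(
        n_collectors=n_collectors,
        divided_diameter=d_div,
        total_ratio=n_collectors * per,
        per_collector_ratio=per,
    )


def calibrate_height(
    observed_CR: float,
    scenario_without_height: CaptureScenario,
    surface: EfficiencySurface,
) -> float:
    """Solve CR = eta * C_p * U * h_c * D_c for the exposed height h_c.

    Used when the exposed collector length was not reported: the height is
    chosen to reproduce an observed contact rate exactly.  ``observed_CR = 0``
    returns 0.0 (degenerate).  The height stored on the input scenario is
    ignored.
    """
    if observed_CR < 0:
        raise ValueError("observed_CR must be >= 0")
    if observed_CR == 0:
        return 0.0
    s = scenario_without_height
    eta = surface.eta_at(s.reynolds, s.size_ratio)
    if eta == 0:
        raise ValueError("cannot calibrate height where eta = 0")
    return observed_CR / (
        eta * s.particle_concentration * s.velocity * s.collector_diameter
    )
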