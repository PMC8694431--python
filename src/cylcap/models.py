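"""Closed-form contact-efficiency models for a rigid cylindrical collector.

Direct interception of neutrally-buoyant spherical particles by a cylinder in
a uniform crossflow is governed by two dimensionless numbers: the collector
Reynolds number Re = U_inf * D_c / nu and the particle size ratio
r_p = D_p / D_c.  The contact efficiency eta(Re, r_p) is the fraction of
particles passing through the collector's upstream projected window
(width D_c) whose centers come within one particle radius of the collector
surface.

Three closed forms cover limiting corners of the (Re, r_p) plane:

* creeping flow (Re << 1): a logarithmic-in-Re form derived from the
  Lamb/Oseen solution for slow flow past a cylinder, here with the full
  finite-particle-size flux integral G(r_p) rather than only its r_p^2 limit;
* boundary-layer theory (Re >> 1, r_p << 1): eta = k1 * Re^0.5 * r_p^2;
* an empirical power-law fit to flume measurements on rigid cylinders,
  eta = 0.224 * Re^0.718 * r_p^2.08, valid for 38 < Re < 486 and r_p < 0.03.

A fourth form, potential (inviscid) flow, is included as an analytic oracle
for the trajectory integrator; it is not a realistic capture model at the
Reynolds numbers of interest but its critical-streamline flux is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CREEPING_CONSTANT",
    "CREEPING_RE_MAX",
    "DimensionlessState",
    "PowerLawModel",
    "RegimeBoundaries",
    "EMPIRICAL_FIT",
    "BOUNDARY_LAYER_EXPONENTS",
    "FlaggedEfficiency",
    "creeping_shape_factor",
    "creeping_flow_eta",
    "creeping_flow_eta_small_rp",
    "boundary_layer_eta",
    "empirical_eta",
    "empirical_in_validity",
    "potential_flow_eta",
    "power_law_eta",
    "flow_regime",
]

#: Constant in the creeping-flow denominator S(Re) = CREEPING_CONSTANT - ln Re.
#: The classical slow-viscous-flow result for a cylinder; configurable because
#: nearby literature rounds it to 2.0.
CREEPING_CONSTANT = 2.002

#: Validity ceiling adopted for the creeping closed form.  Positivity of the
#: denominator requires Re < exp(CREEPING_CONSTANT) ~ 7.4; a margin is kept.
CREEPING_RE_MAX = 5.0


@dataclass(frozen=True)
class DimensionlessState:
    """The (Re, r_p) pair that governs contact efficiency.

    Parameters
    ----------
    reynolds
        Collector Reynolds number, Re = U_inf * D_c / nu.
    size_ratio
        Particle size ratio, r_p = D_p / D_c.
    """

    reynolds: float
    size_ratio: float

    def __post_init__(self) -> None:
        if self.reynolds < 0:
            raise ValueError(f"reynolds must be >= 0, got {self.reynolds}")
        if self.size_ratio < 0:
            raise ValueError(f"size_ratio must be >= 0, got {self.size_ratio}")

    @classmethod
    def from_dimensional(
        cls,
        velocity: float,
        collector_diameter: float,
        particle_diameter: float,
        kinematic_viscosity: float,
    ) -> "DimensionlessState":
        """Build the state from dimensional inputs (any consistent units)."""
        return cls(
            reynolds=velocity * collector_diameter / kinematic_viscosity,
            size_ratio=particle_diameter / collector_diameter,
        )


@dataclass(frozen=True)
class PowerLawModel:
    """A local power-law efficiency model eta = k * Re^alpha * r_p^beta."""

    coefficient: float
    alpha_exponent: float
    beta_exponent: float
    validity_re: tuple[float, float] = (0.0, math.inf)
    validity_rp: tuple[float, float] = (0.0, math.inf)

    def __post_init__(self) -> None:
        if self.coefficient <= 0:
            raise ValueError("coefficient must be > 0")
        if self.validity_re[0] > self.validity_re[1]:
            raise ValueError("empty Re validity interval")
        if self.validity_rp[0] > self.validity_rp[1]:
            raise ValueError("empty r_p validity interval")

    def in_validity(self, state: DimensionlessState) -> bool:
        return (
            self.validity_re[0] < state.reynolds < self.validity_re[1]
            and self.validity_rp[0] < state.size_ratio < self.validity_rp[1]
        )


#: Empirical rigid-cylinder fit: eta = 0.224 Re^0.718 r_p^2.08,
#: fitted over 38 < Re < 486 and r_p < 0.03.
EMPIRICAL_FIT = PowerLawModel(
    coefficient=0.224,
    alpha_exponent=0.718,
    beta_exponent=2.08,
    validity_re=(38.0, 486.0),
    validity_rp=(0.0, 0.03),
)

#: Exponents fixed by boundary-layer theory (the coefficient k1 is free).
BOUNDARY_LAYER_EXPONENTS = (0.5, 2.0)


@dataclass(frozen=True)
class RegimeBoundaries:
    """Flow regimes around a circular cylinder, indexed by Reynolds number.

    The flow is steady and two-dimensional up to Re = 47, sheds a 2-D vortex
    street up to Re = 180, then transitions through two distinct 3-D
    shedding modes (mode A to Re = 260, mode B to Re = 1000).  These
    thresholds act as differencing barriers for local-exponent estimation
    because efficiency is discontinuous across them.
    """

    thresholds: tuple[float, ...] = (47.0, 180.0, 260.0, 1000.0)
    names: tuple[str, ...] = (
        "steady-2D",
        "shedding-2D",
        "shedding-3D-A",
        "shedding-3D-B",
    )

    def __post_init__(self) -> None:
        if list(self.thresholds) != sorted(set(self.thresholds)):
            raise ValueError("thresholds must be strictly increasing")
        if len(self.names) != len(self.thresholds):
            raise ValueError("one name per threshold required")

    def classify(self, reynolds: float) -> str:
        """Regime label for a Reynolds number; intervals are (lo, hi]."""
        if reynolds < 0:
            raise ValueError("Re must be >= 0")
        if reynolds > self.thresholds[-1]:
            raise ValueError(
                f"Re = {reynolds} exceeds the model ceiling "
                f"Re = {self.thresholds[-1]}"
            )
        for hi, name in zip(self.thresholds, self.names):
            if reynolds <= hi:
                return name
        raise AssertionError("unreachable")

    def regime_index(self, reynolds: float) -> int:
        return self.names.index(self.classify(reynolds))


DEFAULT_REGIMES = RegimeBoundaries()


def flow_regime(reynolds: float) -> str:
    """Classify 0 <= Re <= 1000 into the four cylinder-wake regimes."""
    return DEFAULT_REGIMES.classify(reynolds)


@dataclass(frozen=True)
class FlaggedEfficiency:
    """An efficiency value carrying a validity flag.

    ``float(result)`` returns the value, so flagged results interoperate
    with plain arithmetic.
    """

    value: float
    in_validity: bool
    note: str = ""

    def __float__(self) -> float:
        return float(self.value)


def creeping_shape_factor(size_ratio):
    """Finite-size flux factor G(r_p) of the creeping-flow model.

    G(r_p) = 2 (1 + r_p) ln(1 + r_p) - (1 + r_p) + 1/(1 + r_p);
    G ~ 2 r_p^2 as r_p -> 0.  Accepts scalars or arrays.
    """
    rp = np.asarray(size_ratio, dtype=float)
    one = 1.0 + rp
    out = 2.0 * one * np.log1p(rp) - one + 1.0 / one
    return out if out.ndim else float(out)


def _creeping_denominator(reynolds, constant: float) -> float:
    s = constant - np.log(reynolds)
    return s


def creeping_flow_eta(
    state: DimensionlessState, *, constant: float = CREEPING_CONSTANT
) -> float:
    """Finite-size creeping-flow contact efficiency.

    eta = G(r_p) / (2 (constant - ln Re)), valid for 0 < Re <= 5.
    """
    re, rp = state.reynolds, state.size_ratio
    if not 0 < re <= CREEPING_RE_MAX:
        raise ValueError(
            f"creeping-flow form requires 0 < Re <= {CREEPING_RE_MAX} "
            f"(denominator positivity and validity of the slow-flow "
            f"approximation); got Re = {re}"
        )
    if rp < 0:
        raise ValueError("size_ratio must be >= 0")
    if rp == 0:
        return 0.0
    return creeping_shape_factor(rp) / (2.0 * _creeping_denominator(re, constant))


def creeping_flow_eta_small_rp(
    state: DimensionlessState, *, constant: float = CREEPING_CONSTANT
) -> float:
    """Vanishing-size limit of the creeping form: eta = r_p^2 / (c - ln Re)."""
    re, rp = state.reynolds, state.size_ratio
    if not 0 < re <= CREEPING_RE_MAX:
        raise ValueError(f"requires 0 < Re <= {CREEPING_RE_MAX}, got {re}")
    return rp**2 / _creeping_denominator(re, constant)


def boundary_layer_eta(
    state: DimensionlessState, model: PowerLawModel | None = None, *, k1: float = 1.0
) -> FlaggedEfficiency:
    """Boundary-layer contact efficiency eta = k1 * Re^0.5 * r_p^2.

    Nominally valid for Re >= 500 and r_p <= 0.05.  Out-of-validity inputs
    return a flagged value rather than raising, because the surrogate
    surface must evaluate the form near (and across) the validity edge.
    """
    if model is not None:
        if (model.alpha_exponent, model.beta_exponent) != BOUNDARY_LAYER_EXPONENTS:
            raise ValueError(
                "boundary-layer theory fixes (alpha, beta) = (0.5, 2)"
            )
        k1 = model.coefficient
    re, rp = state.reynolds, state.size_ratio
    if re < 0 or rp < 0:
        raise ValueError("Re and r_p must be >= 0")
    ok = re >= 500.0 and rp <= 0.05
    note = "" if ok else "outside nominal validity (Re >= 500, r_p <= 0.05)"
    return FlaggedEfficiency(k1 * math.sqrt(re) * rp**2, ok, note)


def empirical_eta(state: DimensionlessState) -> FlaggedEfficiency:
    """Empirical rigid-cylinder fit eta = 0.224 Re^0.718 r_p^2.08.

    The returned flag records whether (Re, r_p) lies inside the fitted range
    38 < Re < 486, r_p < 0.03.
    """
    re, rp = state.reynolds, state.size_ratio
    if re < 0 or rp < 0:
        raise ValueError("Re and r_p must be >= 0")
    m = EMPIRICAL_FIT
    value = 0.0 if rp == 0 else m.coefficient * re**m.alpha_exponent * rp**m.beta_exponent
    return FlaggedEfficiency(value, m.in_validity(state))


def empirical_in_validity(state: DimensionlessState) -> bool:
    return EMPIRICAL_FIT.in_validity(state)


def potential_flow_eta(size_ratio: float) -> float:
    """Interception efficiency in potential flow past a cylinder.

    Flux between the stagnation streamline and the streamline grazing the
    contact circle of radius (D_c + D_p)/2, normalized by U_inf * D_c:
    eta = (1 + r_p) - 1/(1 + r_p).  For small r_p, eta ~ 2 r_p.
    """
    if size_ratio < 0:
        raise ValueError("size_ratio must be >= 0")
    one = 1.0 + size_ratio
    return one - 1.0 / one


def power_law_eta(model: PowerLawModel, state: DimensionlessState) -> float:
    """Evaluate eta = k * Re^alpha * r_p^beta."""
    if state.size_ratio == 0:
        return 0.0 if model.beta_exponent > 0 else model.coefficient
    return (
        model.coefficient
        * state.reynolds**model.alpha_exponent
        * state.size_ratio**model.beta_exponent
    )
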