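"""Emulations of published particle-capture experiments.

Five experimental comparisons anchor the capture model to observation:

1. contact rate vs flow velocity on flexible polychaete palps (with a
   pronation warning above 6 cm/s, where bent palps defeat the rigid model);
2. size-selective capture by brittle-star tube feet from a settling
   suspension (size-distribution bookkeeping over a ~3 minute run);
3. the large/small particle contact-rate ratio on spionid polychaete palps;
4. normalized contact rate vs branch diameter on red-algae-type structures;
5. contact rate vs velocity and diameter on rigid cylinders in a flume.

Raw observational data are not redistributed; these emulations run the
*model side* of each comparison on configuration fixtures that transcribe
the published experimental conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .models import DimensionlessState, creeping_shape_factor
from .surface import EfficiencySurface
from .contact import CaptureScenario, approaching_flux, predict_contact
from .units import CM_PER_S, MICRON, WATER_KINEMATIC_VISCOSITY

__all__ = [
    "SizeDistribution",
    "StokesSettling",
    "ExperimentConfig",
    "CapturedDistribution",
    "evolve_suspension",
    "captured_distribution",
    "capture_ratio",
    "normalized_CR_vs_diameter",
    "pronation_guard",
    "PRONATION_THRESHOLD_CM_S",
]

#: Flow speed above which flexible palps pronate and the rigid-collector
#: model overestimates contact [cm/s].
PRONATION_THRESHOLD_CM_S = 6.0


@dataclass(frozen=True)
class SizeDistribution:
    """Binned particle concentration by diameter at one instant.

    ``bin_edges`` in micrometres (uniform 10-um bins by convention),
    ``concentration`` in particles/m^3 per bin, ``timestamp`` in seconds.
    """

    bin_edges: np.ndarray
    concentration: np.ndarray
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_edges", np.asarray(self.bin_edges, float))
        object.__setattr__(
            self, "concentration", np.asarray(self.concentration, float)
        )
        if self.bin_edges.ndim != 1 or self.bin_edges.size < 2:
            raise ValueError("need at least one bin")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be increasing (contiguous bins)")
        if self.concentration.shape != (self.bin_edges.size - 1,):
            raise ValueError("one concentration per bin required")
        if np.any(self.concentration < 0):
            raise ValueError("concentrations must be >= 0")

    @property
    def midpoints_um(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total_concentration(self) -> float:
        return float(self.concentration.sum())

    @property
    def peak_diameter_um(self) -> float:
        """Midpoint of the most populated bin."""
        return float(self.midpoints_um[int(np.argmax(self.concentration))])

    @property
    def mean_diameter_um(self) -> float:
        c = self.concentration
        if c.sum() == 0:
            return float("nan")
        return float(np.average(self.midpoints_um, weights=c))


@dataclass(frozen=True)
class StokesSettling:
    """Well-mixed exponential depletion of a suspension by Stokes settling.

    Each bin depletes as exp(-w_s(D) * t / depth) with w_s the Stokes
    settling speed at the bin midpoint:
    w_s = excess_density * g * D^2 / (18 * dynamic_viscosity).

    Defaults (excess density 150 kg/m^3, depth 0.3 m) are a calibration
    fixture: they shift a broad suspended peak from the 150-160 um bin to
    the 110-120 um bin over a 180 s run.
    """

    excess_density: float = 150.0  # kg/m^3 above the fluid
    depth: float = 0.3  # m, effective mixed depth
    dynamic_viscosity: float = 1.0e-3  # Pa s
    gravity: float = 9.81  # m/s^2

    def __post_init__(self) -> None:
        if self.excess_density < 0:
            raise ValueError("excess_density must be >= 0 (neutral or denser)")
        if self.depth <= 0 or self.dynamic_viscosity <= 0 or self.gravity <= 0:
            raise ValueError("depth, viscosity and gravity must be > 0")

    def settling_speed(self, diameter_m):
        """Stokes settling speed [m/s] for particle diameter(s) in metres."""
        d = np.asarray(diameter_m, float)
        w = self.excess_density * self.gravity * d**2 / (18.0 * self.dynamic_viscosity)
        return w if w.ndim else float(w)


def evolve_suspension(
    dist: SizeDistribution, settling: StokesSettling, dt: float
) -> SizeDistribution:
    """Advance a suspension by dt seconds of well-mixed Stokes settling.

    Total concentration is non-increasing and larger bins deplete faster
    (depletion-rate exponent scales with D^2).  dt = 0 is the identity.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    w = settling.settling_speed(dist.midpoints_um * MICRON)
    factor = np.exp(-np.asarray(w) * dt / settling.depth)
    return SizeDistribution(
        bin_edges=dist.bin_edges,
        concentration=dist.concentration * factor,
        timestamp=dist.timestamp + dt,
    )


@dataclass(frozen=True)
class CapturedDistribution:
    """Per-bin capture counts accumulated over an experimental run."""

    bin_edges: np.ndarray
    counts: np.ndarray
    duration: float

    @property
    def midpoints_um(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def peak_diameter_um(self) -> float:
        return float(self.midpoints_um[int(np.argmax(self.counts))])

    @property
    def mean_diameter_um(self) -> float:
        if self.counts.sum() == 0:
            return float("nan")
        return float(np.average(self.midpoints_um, weights=self.counts))

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo_um": self.bin_edges[:-1],
                "bin_hi_um": self.bin_edges[1:],
                "captured_count": self.counts,
            }
        )


def captured_distribution(
    dist_series: list[SizeDistribution],
    scenario_template: CaptureScenario,
    surface: EfficiencySurface,
    dt: float,
) -> CapturedDistribution:
    """Accumulate capture counts per size bin over a time series.

    For each step and bin: count += eta(Re, r_p_bin) * C_bin * U * h_c * D_c * dt.
    The scenario template fixes collector and flow; its particle diameter and
    concentration are replaced bin by bin.  A bin whose (Re, r_p) falls
    outside the surface raises an error naming the bin.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if not dist_series:
        raise ValueError("empty distribution series")
    edges = dist_series[0].bin_edges
    counts = np.zeros(edges.size - 1)
    mids_m = dist_series[0].midpoints_um * MICRON
    # efficiency is time-invariant per bin; compute once
    eta_bin = np.empty(mids_m.size)
    for b, d_m in enumerate(mids_m):
        try:
            sc = replace(
                scenario_template, particle_diameter=d_m, particle_concentration=1.0
            )
            eta_bin[b] = surface.eta_at(sc.reynolds, sc.size_ratio)
        except ValueError as exc:
            raise ValueError(
                f"bin {b} ({edges[b]:g}-{edges[b+1]:g} um): {exc}"
            ) from exc
    window = (
        scenario_template.velocity
        * scenario_template.collector_height
        * scenario_template.collector_diameter
    )
    for dist in dist_series:
        if not np.array_equal(dist.bin_edges, edges):
            raise ValueError("all distributions must share the same bins")
        counts += eta_bin * dist.concentration * window * dt
    return CapturedDistribution(
        bin_edges=edges, counts=counts, duration=len(dist_series) * dt
    )


@dataclass(frozen=True)
class ExperimentConfig:
    """One published experiment's configuration, as printed (Table-style).

    Ranges are (lo, hi) in the stated units; ``estimated`` names fields whose
    values were not reported in the original study and were estimated from
    other literature.
    """

    label: str
    velocity_range_cm_s: tuple[float, float]
    collector_diameters_um: tuple[float, ...]
    particle_diameters_um: tuple[float, ...]
    re_range: tuple[float, float]
    rp_range: tuple[float, float]
    marker: str
    estimated: frozenset = frozenset()

    def implied_re_range(self, nu: float = WATER_KINEMATIC_VISCOSITY):
        u = np.array(self.velocity_range_cm_s) * CM_PER_S
        d = np.array(self.collector_diameters_um) * MICRON
        prod = np.outer(u, d) / nu
        return float(prod.min()), float(prod.max())

    def implied_rp_range(self):
        dp = np.array(self.particle_diameters_um)
        dc = np.array(self.collector_diameters_um)
        ratio = np.outer(dp, 1.0 / dc)
        return float(ratio.min()), float(ratio.max())

    def check_consistency(self, nu: float = WATER_KINEMATIC_VISCOSITY) -> dict:
        """Verify printed Re/r_p ranges against the dimensional columns.

        The printed ranges come from the experiments' actual velocity/
        diameter pairings, which need not be the outer product of the
        printed columns; each printed endpoint must therefore lie inside the
        outer-product interval expanded by one unit in that endpoint's last
        printed digit.  Returns per-endpoint diagnostics; ``ok`` is the
        overall verdict.
        """
        results = {}
        for name, printed, implied in (
            ("Re", self.re_range, self.implied_re_range(nu)),
            ("r_p", self.rp_range, self.implied_rp_range()),
        ):
            lo_ok = printed[0] >= implied[0] - _printed_unit(printed[0])
            hi_ok = printed[1] <= implied[1] + _printed_unit(printed[1])
            results[name] = {
                "printed": printed,
                "implied": implied,
                "lo_ok": bool(lo_ok),
                "hi_ok": bool(hi_ok),
            }
        results["ok"] = all(r["lo_ok"] and r["hi_ok"] for r in (results["Re"], results["r_p"]))
        return results


def _printed_unit(value: float) -> float:
    """One unit in the last significant digit of a printed number.

    0.26 -> 0.01, 8.7 -> 0.1, 14 -> 1, 460 -> 10 (trailing zeros in
    integers are treated as insignificant).
    """
    if value == 0:
        return 1.0
    s = f"{abs(value):.10g}"
    if "." in s:
        return 10.0 ** -(len(s) - s.index(".") - 1)
    n_trailing = len(s) - len(s.rstrip("0"))
    return 10.0**n_trailing


def capture_ratio(
    d_large_um: float,
    d_small_um: float,
    collector_diameter_um: float,
    *,
    surface: EfficiencySurface | None = None,
    velocity_cm_s: float | None = None,
    nu: float = WATER_KINEMATIC_VISCOSITY,
) -> float:
    """Contact-rate ratio CR_large / CR_small for two particle sizes.

    At equal concentrations the approaching-flux factors cancel, so the
    ratio reduces to eta(Re, r_p_large) / eta(Re, r_p_small) — independent
    of C_p and h_c.  Without a surface, the finite-size creeping-flow form
    is used, whose logarithmic Re factor also cancels: the ratio is then
    G(r_p_large)/G(r_p_small), a function of the size ratios alone.
    """
    if d_large_um <= 0 or d_small_um <= 0 or collector_diameter_um <= 0:
        raise ValueError("diameters must be > 0")
    rp_l = d_large_um / collector_diameter_um
    rp_s = d_small_um / collector_diameter_um
    if surface is None:
        return float(creeping_shape_factor(rp_l) / creeping_shape_factor(rp_s))
    if velocity_cm_s is None:
        raise ValueError("velocity_cm_s required for surface-based ratios")
    re = velocity_cm_s * CM_PER_S * collector_diameter_um * MICRON / nu
    return surface.eta_at(re, rp_l) / surface.eta_at(re, rp_s)


def normalized_CR_vs_diameter(
    diameters_um,
    surface: EfficiencySurface,
    *,
    velocity_cm_s: float = 5.0,
    particle_diameter_um: float = 212.0,
    nu: float = WATER_KINEMATIC_VISCOSITY,
) -> pd.DataFrame:
    """Contact rate per collector diameter, relative to the smallest.

    The ambient particle concentration (unreported in the field study this
    emulates) cancels in the normalization, as do h_c and C_p.  Defaults:
    mean bivalve-spat diameter 212 um and mean velocity 5 cm/s.
    """
    diameters = np.sort(np.asarray(diameters_um, float))
    if np.any(diameters <= 0):
        raise ValueError("diameters must be > 0")
    rates = []
    for d_um in diameters:
        sc = CaptureScenario.from_eco(
            velocity_cm_s=velocity_cm_s,
            collector_diameter_um=float(d_um),
            particle_diameter_um=particle_diameter_um,
            collector_height_m=1.0,
            particle_concentration_per_m3=1.0,
            kinematic_viscosity=nu,
        )
        rates.append(predict_contact(sc, surface).contact_rate)
    rates = np.array(rates)
    return pd.DataFrame(
        {
            "D_c_um": diameters,
            "CR_relative": rates / rates[0],
        }
    )


def pronation_guard(
    velocity_cm_s: float, threshold_cm_s: float = PRONATION_THRESHOLD_CM_S
) -> bool:
    """True when flow exceeds the pronation threshold (exclusive).

    Above this speed flexible collectors bend, reducing projected area, and
    rigid-collector predictions overestimate contact rates.
    """
    if velocity_cm_s < 0:
        raise ValueError("velocity must be >= 0")
    return velocity_cm_s > threshold_cm_s
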