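"""Synthetic inputs for end-to-end testing without external data.

Three generator families:

* suspensions — lognormal particle size distributions binned on a 10-um
  grid, emulating a flume seeded with a broad band of particle sizes
  (peak near 150 um for the brittle-star conditions);
* power-law efficiency surfaces with known exponents, the ground truth for
  exponent-recovery tests;
* experiment-configuration fixtures transcribing the published summary
  table of the five analyzed studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .models import DEFAULT_REGIMES, PowerLawModel
from .surface import EfficiencySurface, GridSpec
from .experiments import ExperimentConfig, SizeDistribution

__all__ = [
    "SuspensionSpec",
    "make_suspension",
    "make_powerlaw_surface",
    "make_table3_fixtures",
    "configs_to_yaml",
    "configs_from_yaml",
]


@dataclass(frozen=True)
class SuspensionSpec:
    """Specification of a synthetic suspended-particle population.

    ``peak_diameter_um`` is the mode of the underlying lognormal density;
    ``spread`` its log-space sigma.  ``noise_cv`` adds seeded multiplicative
    per-bin jitter (coefficient of variation); 0 gives the exact binned
    lognormal.
    """

    peak_diameter_um: float = 150.0
    spread: float = 0.5
    total_concentration: float = 2.0e7  # particles/m^3
    bin_lo_um: float = 40.0
    bin_hi_um: float = 320.0
    bin_width_um: float = 10.0
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.bin_lo_um < self.peak_diameter_um < self.bin_hi_um:
            raise ValueError(
                f"peak diameter {self.peak_diameter_um} um outside the bin "
                f"range [{self.bin_lo_um}, {self.bin_hi_um}] um"
            )
        if self.spread <= 0 or self.total_concentration <= 0:
            raise ValueError("spread and total_concentration must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def make_suspension(spec: SuspensionSpec) -> SizeDistribution:
    """Generate a binned lognormal suspension; deterministic given the seed.

    The lognormal is parameterized so its density mode equals
    ``peak_diameter_um``; bin masses are exact cdf differences, rescaled so
    the total concentration matches the spec.
    """
    from scipy.stats import lognorm

    edges = np.arange(
        spec.bin_lo_um, spec.bin_hi_um + 0.5 * spec.bin_width_um, spec.bin_width_um
    )
    sigma = spec.spread
    scale = spec.peak_diameter_um * np.exp(sigma**2)  # median from the mode
    mass = np.diff(lognorm(sigma, scale=scale).cdf(edges))
    if spec.noise_cv > 0:
        rng = np.random.default_rng(spec.seed)
        mass = mass * rng.lognormal(
            -0.5 * np.log1p(spec.noise_cv**2), np.sqrt(np.log1p(spec.noise_cv**2)), mass.size
        )
    conc = mass / mass.sum() * spec.total_concentration
    return SizeDistribution(bin_edges=edges, concentration=conc, timestamp=0.0)


def make_powerlaw_surface(
    alpha0: float,
    beta0: float,
    k0: float,
    grid: GridSpec | None = None,
) -> EfficiencySurface:
    """Exact power-law surface eta = k0 * Re^alpha0 * r_p^beta0.

    Ground truth for exponent recovery: log-space differencing is exact on
    pure power laws, so recovered exponents must equal (alpha0, beta0) to
    rounding error.
    """
    grid = grid or GridSpec()
    re = grid.re_values()
    rp = grid.rp_values()
    eta = k0 * np.outer(re**alpha0, rp**beta0)
    tags = np.full(eta.shape, "power-law", dtype=object)
    labels = [
        DEFAULT_REGIMES.classify(min(r, DEFAULT_REGIMES.thresholds[-1])) for r in re
    ]
    return EfficiencySurface(
        re_grid=re,
        rp_grid=rp,
        eta=eta,
        regime_label=labels,
        source_tag=tags,
        meta={"alpha0": alpha0, "beta0": beta0, "k0": k0},
    )


def make_table3_fixtures() -> list[ExperimentConfig]:
    """Configurations of the five published experiments, as printed.

    Values flagged ``estimated`` were not reported in the original studies
    and were estimated from other literature.
    """
    return [
        ExperimentConfig(
            label="spionid-polychaetes-velocity",
            velocity_range_cm_s=(3.0, 12.0),
            collector_diameters_um=(70.0, 120.0),
            particle_diameters_um=(32.0,),
            re_range=(2.1, 14.0),
            rp_range=(0.26, 0.5),
            marker="triangle-up",
            estimated=frozenset({"collector_diameters_um"}),
        ),
        ExperimentConfig(
            label="brittle-star",
            velocity_range_cm_s=(4.0, 4.0),
            collector_diameters_um=(217.0,),
            particle_diameters_um=(40.0, 320.0),
            re_range=(8.7, 8.7),
            rp_range=(0.18, 1.5),
            marker="star",
        ),
        ExperimentConfig(
            label="spionid-polychaetes-size",
            velocity_range_cm_s=(1.3, 9.1),
            collector_diameters_um=(60.0, 200.0),
            particle_diameters_um=(32.0, 82.0),
            re_range=(0.7, 18.0),
            rp_range=(0.15, 1.4),
            marker="triangle-down",
        ),
        ExperimentConfig(
            label="red-algae-structure",
            velocity_range_cm_s=(5.0, 5.0),
            collector_diameters_um=(500.0, 1700.0),
            particle_diameters_um=(200.0,),
            re_range=(25.0, 70.0),
            rp_range=(0.12, 0.4),
            marker="asterisk",
            estimated=frozenset({"velocity_range_cm_s", "particle_diameters_um"}),
        ),
        ExperimentConfig(
            label="rigid-cylinder",
            velocity_range_cm_s=(0.6, 1.8),
            collector_diameters_um=(6350.0, 12700.0, 25400.0),
            particle_diameters_um=(194.0,),
            re_range=(38.0, 460.0),
            rp_range=(0.008, 0.03),
            marker="square/diamond/circle",
        ),
    ]


def configs_to_yaml(configs: list[ExperimentConfig], path) -> None:
    """Serialize configuration fixtures to a YAML bundle."""
    payload = [
        {
            "label": c.label,
            "velocity_range_cm_s": list(c.velocity_range_cm_s),
            "collector_diameters_um": list(c.collector_diameters_um),
            "particle_diameters_um": list(c.particle_diameters_um),
            "re_range": list(c.re_range),
            "rp_range": list(c.rp_range),
            "marker": c.marker,
            "estimated": sorted(c.estimated),
        }
        for c in configs
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def configs_from_yaml(path) -> list[ExperimentConfig]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return [
        ExperimentConfig(
            label=d["label"],
            velocity_range_cm_s=tuple(d["velocity_range_cm_s"]),
            collector_diameters_um=tuple(d["collector_diameters_um"]),
            particle_diameters_um=tuple(d["particle_diameters_um"]),
            re_range=tuple(d["re_range"]),
            rp_range=tuple(d["rp_range"]),
            marker=d["marker"],
            estimated=frozenset(d.get("estimated", [])),
        )
        for d in payload
    ]
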