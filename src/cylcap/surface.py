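"""Gridded contact-efficiency surfaces over the (Re, r_p) parameter plane.

The ecological parameter space — 0.01 <= Re <= 1000 and 0 < r_p <= 1.5 — is
wider than the validity range of any single closed-form efficiency model, so
predictions are served from an :class:`EfficiencySurface`: efficiency tabulated
on a log-spaced grid with per-cell provenance.  The built-in surrogate surface
stitches the three closed forms together:

====================  ============================================
Re band               source
====================  ============================================
Re <= 5               finite-size creeping-flow form
5 < Re < 38           log-log-linear blend (per r_p column)
38 <= Re <= 486       empirical rigid-cylinder power law
486 < Re < 500        log-log-linear blend (per r_p column)
Re >= 500             boundary-layer form, k1 calibrated at Re=500
====================  ============================================

The stitched function is continuous in Re by construction.  A user-supplied
efficiency table (three-column CSV) can override computed cells, e.g. with
values digitized from simulation output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .models import (
    CREEPING_CONSTANT,
    DEFAULT_REGIMES,
    DimensionlessState,
    EMPIRICAL_FIT,
    RegimeBoundaries,
    creeping_flow_eta,
    empirical_eta,
)

__all__ = [
    "GridSpec",
    "StitchParams",
    "EfficiencySurface",
    "calibrate_k1",
    "surrogate_eta",
    "build_surrogate_surface",
    "read_user_table",
]


@dataclass(frozen=True)
class GridSpec:
    """Log-spaced evaluation grid for an efficiency surface.

    Defaults: 51 Re points over 0.01–1000 (10 per decade) and 40 r_p points
    over 0.005–1.5.
    """

    re_min: float = 0.01
    re_max: float = 1000.0
    n_re: int = 51
    rp_min: float = 0.005
    rp_max: float = 1.5
    n_rp: int = 40

    def __post_init__(self) -> None:
        if not 0 < self.re_min < self.re_max:
            raise ValueError("need 0 < re_min < re_max")
        if not 0 < self.rp_min < self.rp_max:
            raise ValueError("need 0 < rp_min < rp_max")
        decades = math.log10(self.re_max / self.re_min)
        if (self.n_re - 1) / decades < 10.0 - 1e-9:
            raise ValueError(
                f"grid must provide >= 10 Re points per logarithmic decade; "
                f"{self.n_re} points over {decades:.2f} decades is too coarse"
            )
        if self.n_rp < 3:
            raise ValueError("need at least 3 r_p points")

    def re_values(self) -> np.ndarray:
        return np.geomspace(self.re_min, self.re_max, self.n_re)

    def rp_values(self) -> np.ndarray:
        return np.geomspace(self.rp_min, self.rp_max, self.n_rp)


@dataclass(frozen=True)
class StitchParams:
    """Junction Reynolds numbers and constants of the stitched surrogate."""

    creeping_constant: float = CREEPING_CONSTANT
    creeping_re_max: float = 5.0
    empirical_re_min: float = 38.0
    empirical_re_max: float = 486.0
    boundary_layer_re_min: float = 500.0
    #: r_p at which k1 is calibrated against the empirical fit (its validity edge).
    k1_reference_rp: float = 0.03


def calibrate_k1(params: StitchParams = StitchParams()) -> float:
    """Calibrate the boundary-layer coefficient k1 against the empirical fit.

    k1 is set so that k1 * Re^0.5 * r_p^2 equals the empirical power law at
    the junction Re (500 by default) and the reference r_p (0.03, the
    empirical fit's particle-size validity edge).  The remaining per-column
    mismatch over 486 < Re < 500 is absorbed by the blend.
    """
    re0 = params.boundary_layer_re_min
    rp0 = params.k1_reference_rp
    target = float(empirical_eta(DimensionlessState(re0, rp0)))
    return target / (math.sqrt(re0) * rp0**2)


def _source_for_re(re: float, p: StitchParams) -> str:
    if re <= p.creeping_re_max:
        return "creeping"
    if re < p.empirical_re_min:
        return "blended"
    if re <= p.empirical_re_max:
        return "empirical"
    if re < p.boundary_layer_re_min:
        return "blended"
    return "boundary-layer"


def surrogate_eta(
    reynolds, size_ratio, params: StitchParams = StitchParams(), k1: float | None = None
):
    """Evaluate the stitched surrogate efficiency (vectorized over inputs).

    Continuous in Re by construction: the blend bands interpolate ln(eta)
    linearly in ln(Re) between the closed forms at the band edges, within
    each r_p column.
    """
    if k1 is None:
        k1 = calibrate_k1(params)
    re = np.asarray(reynolds, dtype=float)
    rp = np.asarray(size_ratio, dtype=float)
    re, rp = np.broadcast_arrays(re, rp)
    out = np.empty(re.shape, dtype=float)
    it = np.nditer([re, rp], flags=["multi_index"])
    for re_i, rp_i in it:
        out[it.multi_index] = _surrogate_eta_scalar(float(re_i), float(rp_i), params, k1)
    return out if out.ndim else float(out)


def _creep(re: float, rp: float, p: StitchParams) -> float:
    return creeping_flow_eta(
        DimensionlessState(re, rp), constant=p.creeping_constant
    )


def _emp(re: float, rp: float) -> float:
    return float(empirical_eta(DimensionlessState(re, rp)))


def _bl(re: float, rp: float, k1: float) -> float:
    return k1 * math.sqrt(re) * rp**2


def _surrogate_eta_scalar(re: float, rp: float, p: StitchParams, k1: float) -> float:
    if re <= 0:
        raise ValueError("Re must be > 0")
    if rp < 0:
        raise ValueError("r_p must be >= 0")
    if rp == 0.0:
        return 0.0
    if re <= p.creeping_re_max:
        return _creep(re, rp, p)
    if re < p.empirical_re_min:
        lo = _creep(p.creeping_re_max, rp, p)
        hi = _emp(p.empirical_re_min, rp)
        t = math.log(re / p.creeping_re_max) / math.log(
            p.empirical_re_min / p.creeping_re_max
        )
        return math.exp((1 - t) * math.log(lo) + t * math.log(hi))
    if re <= p.empirical_re_max:
        return _emp(re, rp)
    if re < p.boundary_layer_re_min:
        lo = _emp(p.empirical_re_max, rp)
        hi = _bl(p.boundary_layer_re_min, rp, k1)
        t = math.log(re / p.empirical_re_max) / math.log(
            p.boundary_layer_re_min / p.empirical_re_max
        )
        return math.exp((1 - t) * math.log(lo) + t * math.log(hi))
    return _bl(re, rp, k1)


@dataclass
class EfficiencySurface:
    """Contact efficiency tabulated on a log-spaced (Re, r_p) grid.

    Attributes
    ----------
    re_grid, rp_grid
        Strictly increasing axis values; ``eta[i, j]`` corresponds to
        ``(re_grid[i], rp_grid[j])``.
    eta
        Efficiency matrix, shape (len(re_grid), len(rp_grid)).
    regime_label
        Wake-regime tag per Re value.
    source_tag
        Per-cell provenance: one of {"creeping", "empirical",
        "boundary-layer", "blended", "user-table", "power-law"}.
    """

    re_grid: np.ndarray
    rp_grid: np.ndarray
    eta: np.ndarray
    regime_label: list[str]
    source_tag: np.ndarray
    regimes: RegimeBoundaries = field(default_factory=RegimeBoundaries)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.re_grid = np.asarray(self.re_grid, dtype=float)
        self.rp_grid = np.asarray(self.rp_grid, dtype=float)
        self.eta = np.asarray(self.eta, dtype=float)
        self.source_tag = np.asarray(self.source_tag, dtype=object)
        if np.any(np.diff(self.re_grid) <= 0) or np.any(np.diff(self.rp_grid) <= 0):
            raise ValueError("grids must be strictly increasing")
        if self.eta.shape != (self.re_grid.size, self.rp_grid.size):
            raise ValueError("eta shape does not match grids")
        if self.source_tag.shape != self.eta.shape:
            raise ValueError("source_tag shape does not match eta")
        if np.any(self.eta < 0):
            raise ValueError("eta must be non-negative")
        if len(self.regime_label) != self.re_grid.size:
            raise ValueError("one regime label per Re value required")

    # -- interpolation ----------------------------------------------------

    def _locate(self, grid: np.ndarray, value: float, name: str) -> int:
        if not grid[0] <= value <= grid[-1]:
            raise ValueError(
                f"{name} = {value:g} outside surface coverage "
                f"[{grid[0]:g}, {grid[-1]:g}]"
            )
        idx = int(np.searchsorted(grid, value, side="right") - 1)
        return min(idx, grid.size - 2)

    def eta_at(self, reynolds: float, size_ratio: float) -> float:
        """Efficiency by bilinear interpolation in (ln Re, ln r_p, ln eta).

        Raises a coverage error (naming the exceeded bound) outside the grid;
        no silent extrapolation.
        """
        i = self._locate(self.re_grid, reynolds, "Re")
        j = self._locate(self.rp_grid, size_ratio, "r_p")
        tx = math.log(reynolds / self.re_grid[i]) / math.log(
            self.re_grid[i + 1] / self.re_grid[i]
        )
        ty = math.log(size_ratio / self.rp_grid[j]) / math.log(
            self.rp_grid[j + 1] / self.rp_grid[j]
        )
        corners = self.eta[i : i + 2, j : j + 2]
        if np.any(corners <= 0):  # fall back to linear where ln eta undefined
            v = (
                (1 - tx) * (1 - ty) * corners[0, 0]
                + (1 - tx) * ty * corners[0, 1]
                + tx * (1 - ty) * corners[1, 0]
                + tx * ty * corners[1, 1]
            )
            return float(v)
        ln = np.log(corners)
        v = (
            (1 - tx) * (1 - ty) * ln[0, 0]
            + (1 - tx) * ty * ln[0, 1]
            + tx * (1 - ty) * ln[1, 0]
            + tx * ty * ln[1, 1]
        )
        return float(math.exp(v))

    def source_at(self, reynolds: float, size_ratio: float) -> str:
        """Provenance tag of the grid cell nearest to (Re, r_p)."""
        i = self._locate(self.re_grid, reynolds, "Re")
        j = self._locate(self.rp_grid, size_ratio, "r_p")
        if reynolds > math.sqrt(self.re_grid[i] * self.re_grid[i + 1]):
            i += 1
        if size_ratio > math.sqrt(self.rp_grid[j] * self.rp_grid[j + 1]):
            j += 1
        return str(self.source_tag[i, j])

    def restrict(
        self,
        re_range: tuple[float, float] = (0.0, math.inf),
        rp_range: tuple[float, float] = (0.0, math.inf),
    ) -> "EfficiencySurface":
        """Sub-surface with grid nodes strictly inside the given open ranges."""
        mi = (self.re_grid > re_range[0]) & (self.re_grid < re_range[1])
        mj = (self.rp_grid > rp_range[0]) & (self.rp_grid < rp_range[1])
        if mi.sum() < 2 or mj.sum() < 2:
            raise ValueError("restriction leaves fewer than 2 points on an axis")
        return EfficiencySurface(
            re_grid=self.re_grid[mi],
            rp_grid=self.rp_grid[mj],
            eta=self.eta[np.ix_(mi, mj)],
            regime_label=[l for l, keep in zip(self.regime_label, mi) if keep],
            source_tag=self.source_tag[np.ix_(mi, mj)],
            regimes=self.regimes,
            meta=dict(self.meta),
        )

    # -- serialization ----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns Re, r_p, eta, regime, source."""
        ii, jj = np.meshgrid(
            np.arange(self.re_grid.size), np.arange(self.rp_grid.size), indexing="ij"
        )
        return pd.DataFrame(
            {
                "Re": self.re_grid[ii.ravel()],
                "r_p": self.rp_grid[jj.ravel()],
                "eta": self.eta.ravel(),
                "regime": [self.regime_label[i] for i in ii.ravel()],
                "source": self.source_tag.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path) -> "EfficiencySurface":
        df = pd.read_csv(path)
        re_grid = np.array(sorted(df["Re"].unique()))
        rp_grid = np.array(sorted(df["r_p"].unique()))
        eta = df.pivot(index="Re", columns="r_p", values="eta").loc[re_grid, rp_grid]
        src = df.pivot(index="Re", columns="r_p", values="source").loc[re_grid, rp_grid]
        regime = (
            df.drop_duplicates("Re").set_index("Re").loc[re_grid, "regime"].tolist()
        )
        return cls(
            re_grid=re_grid,
            rp_grid=rp_grid,
            eta=eta.to_numpy(),
            regime_label=regime,
            source_tag=src.to_numpy(),
        )

    def to_json(self, path) -> None:
        payload = {
            "re_grid": self.re_grid.tolist(),
            "rp_grid": self.rp_grid.tolist(),
            "eta": self.eta.tolist(),
            "regime_label": list(self.regime_label),
            "source_tag": self.source_tag.astype(str).tolist(),
            "meta": self.meta,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "EfficiencySurface":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            re_grid=np.array(payload["re_grid"]),
            rp_grid=np.array(payload["rp_grid"]),
            eta=np.array(payload["eta"]),
            regime_label=payload["regime_label"],
            source_tag=np.array(payload["source_tag"], dtype=object),
            meta=payload.get("meta", {}),
        )


def read_user_table(path) -> pd.DataFrame:
    """Read a user-supplied (Re, r_p, eta) table (CSV with header).

    Validates: required columns present, grids formed by the unique Re and
    r_p values strictly positive, and eta non-negative.  Offending rows are
    listed in the error.
    """
    df = pd.read_csv(path)
    required = {"Re", "r_p", "eta"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"user table must have columns {sorted(required)}, got {list(df.columns)}"
        )
    bad = df.index[(df["eta"] < 0) | (df["Re"] <= 0) | (df["r_p"] <= 0)].tolist()
    if bad:
        raise ValueError(f"user table has invalid rows (0-based): {bad}")
    if df.duplicated(["Re", "r_p"]).any():
        dup = df.index[df.duplicated(["Re", "r_p"])].tolist()
        raise ValueError(f"user table has duplicate (Re, r_p) rows: {dup}")
    return df


def build_surrogate_surface(
    grid: GridSpec = GridSpec(),
    user_table: pd.DataFrame | None = None,
    params: StitchParams = StitchParams(),
    regimes: RegimeBoundaries = DEFAULT_REGIMES,
) -> EfficiencySurface:
    """Assemble the stitched surrogate efficiency surface on a grid.

    If ``user_table`` is given (columns Re, r_p, eta), each of its points is
    snapped to the nearest grid node in log space and overrides the computed
    value there with source tag "user-table".
    """
    re_grid = grid.re_values()
    rp_grid = grid.rp_values()
    k1 = calibrate_k1(params)
    eta = np.empty((re_grid.size, rp_grid.size))
    tags = np.empty_like(eta, dtype=object)
    for i, re in enumerate(re_grid):
        tag = _source_for_re(re, params)
        for j, rp in enumerate(rp_grid):
            eta[i, j] = _surrogate_eta_scalar(re, rp, params, k1)
            tags[i, j] = tag
    if user_table is not None:
        if isinstance(user_table, (str, bytes)) or hasattr(user_table, "__fspath__"):
            user_table = read_user_table(user_table)
        for _, row in user_table.iterrows():
            i = int(np.argmin(np.abs(np.log(re_grid) - math.log(row["Re"]))))
            j = int(np.argmin(np.abs(np.log(rp_grid) - math.log(row["r_p"]))))
            eta[i, j] = row["eta"]
            tags[i, j] = "user-table"
    labels = [regimes.classify(min(re, regimes.thresholds[-1])) for re in re_grid]
    return EfficiencySurface(
        re_grid=re_grid,
        rp_grid=rp_grid,
        eta=eta,
        regime_label=labels,
        source_tag=tags,
        regimes=regimes,
        meta={"k1": k1, "stitch": params.__dict__.copy()},
    )
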