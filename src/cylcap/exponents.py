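"""Local scaling exponents of contact efficiency and contact rate.

Over any small patch of the (Re, r_p) plane the efficiency behaves like a
power law eta ~ k Re^alpha r_p^beta, so the contact rate
CR = eta * C_p U_inf h_c D_c scales with the dimensional drivers as

    CR ∝ U_inf^gamma  D_p^beta  D_c^delta,
    gamma = 1 + alpha,   delta = 1 + alpha - beta.

The *local* exponents are the log-log slopes of the tabulated surface:

    alpha = ln(eta1/eta2) / ln(Re1/Re2)      at fixed r_p,
    beta  = ln(eta1/eta2) / ln(rp1/rp2)      at fixed Re.

On a grid these are evaluated with centered differences in log space inside
each wake regime, and one-sided differences at grid edges and on either side
of every regime boundary (Re = 47, 180, 260): efficiency is discontinuous
across regime transitions, so no differencing stencil may straddle one.
Cells forced one-sided by a regime boundary are flagged in ``mask``.
Log-space differencing is exact (either variant) wherever the surface is an
exact power law.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import RegimeBoundaries
from .surface import EfficiencySurface

__all__ = ["ExponentFields", "local_alpha", "local_beta", "exponent_maps"]


def _pair_exponent(eta1: float, eta2: float, x1: float, x2: float) -> float:
    if eta1 <= 0 or eta2 <= 0:
        raise ValueError("local exponents undefined where eta <= 0")
    if x1 == x2:
        raise ValueError("local exponents undefined for coincident grid values")
    return float(np.log(eta1 / eta2) / np.log(x1 / x2))


def local_alpha(surface: EfficiencySurface, i1: int, i2: int, j: int) -> float:
    """Pairwise local Re-exponent between grid rows i1 and i2 at column j.

    alpha = ln(eta1/eta2) / ln(Re1/Re2), both cells sharing r_p.
    """
    return _pair_exponent(
        surface.eta[i1, j], surface.eta[i2, j], surface.re_grid[i1], surface.re_grid[i2]
    )


def local_beta(surface: EfficiencySurface, i: int, j1: int, j2: int) -> float:
    """Pairwise local r_p-exponent between grid columns j1 and j2 at row i.

    beta = ln(eta1/eta2) / ln(rp1/rp2), both cells sharing Re.
    """
    return _pair_exponent(
        surface.eta[i, j1], surface.eta[i, j2], surface.rp_grid[j1], surface.rp_grid[j2]
    )


@dataclass
class ExponentFields:
    """Aligned grids of local exponents alpha, beta, gamma, delta.

    ``mask`` is True where the alpha stencil was forced one-sided by a wake
    regime boundary (or where an exponent is undefined); the identities
    gamma = 1 + alpha and delta = 1 + alpha - beta hold cell-wise wherever
    the entries are finite.
    """

    re_grid: np.ndarray
    rp_grid: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    delta: np.ndarray
    mask: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        ii, jj = np.meshgrid(
            np.arange(self.re_grid.size), np.arange(self.rp_grid.size), indexing="ij"
        )
        return pd.DataFrame(
            {
                "Re": self.re_grid[ii.ravel()],
                "r_p": self.rp_grid[jj.ravel()],
                "alpha": self.alpha.ravel(),
                "beta": self.beta.ravel(),
                "gamma": self.gamma.ravel(),
                "delta": self.delta.ravel(),
                "masked": self.mask.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        # masked cells keep NaN markers rather than extrapolated numbers
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    def to_json(self, path) -> None:
        def grid(a):
            return [[None if not np.isfinite(v) else v for v in row] for row in a]

        payload = {
            "re_grid": self.re_grid.tolist(),
            "rp_grid": self.rp_grid.tolist(),
            "alpha": grid(self.alpha),
            "beta": grid(self.beta),
            "gamma": grid(self.gamma),
            "delta": grid(self.delta),
            "mask": self.mask.astype(bool).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _log_slopes_1d(x: np.ndarray, ln_eta: np.ndarray, segments) -> tuple[np.ndarray, np.ndarray]:
    """Log-log slopes along axis 0 of ln_eta, segment by segment.

    ``segments`` is a list of index arrays; no stencil crosses a segment
    edge.  Returns (slopes, boundary_mask) where boundary_mask flags cells
    one-sided because of an interior segment edge (not the global ends).
    """
    n = x.size
    ln_x = np.log(x)
    out = np.full(ln_eta.shape, np.nan)
    bmask = np.zeros(n, dtype=bool)
    for seg in segments:
        lo, hi = seg[0], seg[-1]
        m = len(seg)
        if m < 2:
            bmask[seg] = True
            continue
        if m < 3:
            bmask[seg] = True  # too few points for a trustworthy slope
        for k, idx in enumerate(seg):
            if k == 0:
                i1, i2 = seg[0], seg[1]
            elif k == m - 1:
                i1, i2 = seg[-2], seg[-1]
            else:
                i1, i2 = seg[k - 1], seg[k + 1]
            out[idx] = (ln_eta[i2] - ln_eta[i1]) / (ln_x[i2] - ln_x[i1])
            onesided = k == 0 or k == m - 1
            interior_edge = (k == 0 and lo != 0) or (k == m - 1 and hi != n - 1)
            if onesided and interior_edge:
                bmask[idx] = True
    return out, bmask


def exponent_maps(
    surface: EfficiencySurface, regimes: RegimeBoundaries | None = None
) -> ExponentFields:
    """Compute local exponent fields over an efficiency surface.

    Centered log-space differences interior to each wake regime; one-sided
    at grid edges and on either side of every regime boundary.  Cells whose
    centered stencil would cross a boundary are computed one-sided and
    flagged in ``mask``.  gamma and delta are filled from the identities
    gamma = 1 + alpha, delta = 1 + alpha - beta.
    """
    regimes = regimes or surface.regimes
    re, rp = surface.re_grid, surface.rp_grid
    if np.any(surface.eta <= 0):
        eta_ok = surface.eta > 0
    else:
        eta_ok = np.ones_like(surface.eta, dtype=bool)
    with np.errstate(divide="ignore"):
        ln_eta = np.where(eta_ok, np.log(np.where(eta_ok, surface.eta, 1.0)), np.nan)

    # contiguous runs of grid indices sharing a wake regime
    reg_idx = np.array(
        [regimes.regime_index(min(r, regimes.thresholds[-1])) for r in re]
    )
    segments = []
    start = 0
    for i in range(1, re.size + 1):
        if i == re.size or reg_idx[i] != reg_idx[start]:
            segments.append(np.arange(start, i))
            start = i
    for seg in segments:
        if len(seg) < 3:
            warnings.warn(
                f"wake regime spanning Re {re[seg[0]]:.3g}-{re[seg[-1]]:.3g} has "
                f"only {len(seg)} grid point(s): its cells are one-sided and "
                f"masked",
                stacklevel=2,
            )

    alpha = np.full(surface.eta.shape, np.nan)
    bmask_re = np.zeros(re.size, dtype=bool)
    for j in range(rp.size):
        col, bm = _log_slopes_1d(re, ln_eta[:, j], segments)
        alpha[:, j] = col
        bmask_re |= bm

    beta = np.full(surface.eta.shape, np.nan)
    for i in range(re.size):
        row, _ = _log_slopes_1d(rp, ln_eta[i, :], [np.arange(rp.size)])
        beta[i, :] = row

    mask = np.broadcast_to(bmask_re[:, None], alpha.shape).copy()
    mask |= ~np.isfinite(alpha) | ~np.isfinite(beta)
    gamma = 1.0 + alpha
    delta = 1.0 + alpha - beta
    return ExponentFields(
        re_grid=re.copy(),
        rp_grid=rp.copy(),
        alpha=alpha,
        beta=beta,
        gamma=gamma,
        delta=delta,
        mask=mask,
    )
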