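"""Organ Boyle van't Hoff analysis: steady-state osmotic volumes and r_a estimation.

Perfusing an organ with carrier solutions of different osmolarity M lets
the tissue equilibrate at V = (M_iso/M) V0. Each equilibrium volume maps to
a capillary radius and hence a steady vascular resistance, which yields a
linear relation -- the organ Boyle van't Hoff equation --

    1/sqrt(R)  is affine in  M_iso/M,

whose slope/intercept ratio depends only on the active-volume apothem r_a
and the isotonic capillary radius r_c0. The absolute slope and intercept
carry the unknown number of Krogh units n; the ratio does not, so fits
operate on baseline-normalized resistance and report ratio-derived
quantities only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .krogh import HEX, KroghGeometry, capillary_radius, structural_resistance_norm
from .units import ISOTONIC_OSMOLARITY


@dataclass(frozen=True)
class BvhDataset:
    """Steady normalized structural resistances at several perfusate osmolarities."""

    osmolarities: np.ndarray  # mol/m^3
    R_norm: np.ndarray  # dimensionless, > 0
    M_iso: float = ISOTONIC_OSMOLARITY

    def __post_init__(self) -> None:
        M = np.asarray(self.osmolarities, dtype=float)
        R = np.asarray(self.R_norm, dtype=float)
        object.__setattr__(self, "osmolarities", M)
        object.__setattr__(self, "R_norm", R)
        if M.shape != R.shape:
            raise ValueError("osmolarities and R_norm must have equal length")
        if np.unique(M).size < 2:
            raise ValueError("need >= 2 distinct osmolarities")
        if np.any(M <= 0) or np.any(R <= 0):
            raise ValueError("osmolarities and resistances must be positive")


@dataclass(frozen=True)
class BvhFit:
    """Result of the organ Boyle van't Hoff linear fit."""

    slope: float
    y_intercept: float
    r_a: float  # m
    V_b: float  # osmotically inactive volume fraction
    r_squared: float

    @property
    def ratio(self) -> float:
        return self.slope / self.y_intercept


def equilibrium_volume(M: float, M_iso: float = ISOTONIC_OSMOLARITY, V0: float = 1.0) -> float:
    """Equilibrated active volume under perfusate osmolarity M (Boyle van't Hoff)."""
    if M <= 0:
        raise ValueError("osmolarity must be positive")
    return (M_iso / M) * V0


def bvh_linear_fit(data: BvhDataset) -> tuple[float, float, float]:
    """OLS of 1/sqrt(R_norm) on M_iso/M; returns (slope, y_intercept, r_squared).

    Only the slope/intercept ratio is scale-invariant: renormalizing R
    multiplies both by the same constant.
    """
    x = data.M_iso / data.osmolarities
    y = 1.0 / np.sqrt(data.R_norm)
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    if x.size == 2:
        r2 = 1.0  # exact line through two points
    return float(slope), float(intercept), r2


def r_a_from_fit(slope: float, y_intercept: float, r_c0: float) -> float:
    """Active-volume apothem from the fitted line.

    Inverts slope/intercept = -(2 sqrt3 r_a^2 - pi r_c0^2)/(2 sqrt3 r_a^2):
    r_a = sqrt(pi r_c0^2 / (2 sqrt3 (ratio + 1))).
    """
    ratio = slope / y_intercept
    denom = HEX * (ratio + 1.0)
    if denom <= 0:
        raise ValueError(f"non-physical fit: slope/intercept = {ratio:.4g} <= -1")
    return math.sqrt(math.pi * r_c0**2 / denom)


def inactive_fraction(r_a: float, r_k: float, r_c0: float) -> float:
    """Osmotically inactive volume fraction V_b of the Krogh unit."""
    if not (r_c0 < r_a <= r_k):
        raise ValueError("need r_c0 < r_a <= r_k")
    return HEX * (r_k**2 - r_a**2) / (HEX * r_k**2 - math.pi * r_c0**2)


def fit_r_a(data: BvhDataset, geom: KroghGeometry = KroghGeometry()) -> BvhFit:
    """Full pipeline: linear fit -> r_a -> V_b, using geom for r_c0 and r_k."""
    slope, intercept, r2 = bvh_linear_fit(data)
    r_a = r_a_from_fit(slope, intercept, geom.r_c0)
    V_b = inactive_fraction(r_a, geom.r_k, geom.r_c0) if r_a <= geom.r_k else float("nan")
    return BvhFit(slope=slope, y_intercept=intercept, r_a=r_a, V_b=V_b, r_squared=r2)


def steady_resistance_model(
    M: np.ndarray, geom: KroghGeometry, M_iso: float = ISOTONIC_OSMOLARITY
) -> np.ndarray:
    """Forward steady-state model: R_norm at equilibrium with osmolarity M."""
    M = np.asarray(M, dtype=float)
    if np.any(M <= 0):
        raise ValueError("osmolarity must be positive")
    V = (M_iso / M) * geom.V0
    rc = capillary_radius(V, geom)
    return structural_resistance_norm(rc, geom)


def steady_resistance(
    time_min: np.ndarray,
    Rp_norm: np.ndarray,
    window_min: float = 3.0,
    drift_tol: float = 0.01,
) -> float:
    """Steady resistance from a trace: mean over the terminal window.

    Guards against unsettled traces: the fitted slope over the window,
    expressed as fractional change per minute, must stay below drift_tol.
    """
    t = np.asarray(time_min, dtype=float)
    r = np.asarray(Rp_norm, dtype=float)
    m = t >= t[-1] - window_min
    if m.sum() < 2:
        raise ValueError("terminal window contains fewer than 2 samples")
    slope = np.polyfit(t[m], r[m], 1)[0]
    mean = float(r[m].mean())
    if abs(slope) / mean > drift_tol:
        raise ValueError(
            f"trace not settled: window drift {abs(slope) / mean:.3g}/min exceeds {drift_tol}"
        )
    return mean
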