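"""Toxicity cost-function model and its estimation from slice-viability assays.

Viability under CPA exposure decays exponentially with a concentration-
dependent rate following a power law,

    k = beta * C**alpha        [1/min, C in mol/L]
    N/N0 = exp(-integral k dt) = exp(-J_tox),

so the cumulative cost J_tox = integral beta * C(t)**alpha dt summarizes an
arbitrary concentration history. alpha and beta are CPA- and temperature-
specific; the packaged defaults are for the VMP cocktail at 4 C.

Estimation follows the assay design: tissue slices are step-loaded to a
test concentration, held 15-120 min, unloaded, and assayed; per
concentration a zero-intercept fit of ln(viability) on exposure time gives
k, then a log-log regression of k on C gives (alpha, beta).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ToxicityParams:
    """Power-law toxicity rate constants: k = beta * C**alpha (C in mol/L, k in 1/min)."""

    alpha: float = 3.12
    beta: float = 9.39e-6
    temperature_label: str = "4C"

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")


@dataclass(frozen=True)
class SliceViabilityDataset:
    """Tidy slice-assay table: one row per (concentration, exposure time, replicate)."""

    table: pd.DataFrame  # columns: concentration_M, time_min, replicate, viability

    REQUIRED = ("concentration_M", "time_min", "viability")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if (self.table["viability"] < 0).any():
            raise ValueError("viability must be non-negative")

    def concentrations(self) -> np.ndarray:
        return np.unique(self.table["concentration_M"].to_numpy())


def toxicity_rate(C_M: float | np.ndarray, tox: ToxicityParams) -> float | np.ndarray:
    """Toxicity rate k = beta * C**alpha (1/min) at concentration C (mol/L)."""
    C = np.asarray(C_M, dtype=float)
    if np.any(C < 0):
        raise ValueError("concentration must be non-negative")
    out = tox.beta * C**tox.alpha
    return float(out) if out.ndim == 0 else out


def toxicity_cost(
    time_min: np.ndarray, C_M: np.ndarray, tox: ToxicityParams
) -> float:
    """Cumulative toxicity cost: trapezoidal integral of beta*C(t)**alpha over minutes."""
    t = np.asarray(time_min, dtype=float)
    C = np.asarray(C_M, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time must be strictly increasing")
    if np.any(C < 0):
        raise ValueError("concentration must be non-negative")
    return float(np.trapezoid(toxicity_rate(C, tox), t))


def viability_from_cost(J_tox: float) -> float:
    """Predicted surviving fraction N/N0 = exp(-J_tox)."""
    if J_tox < 0:
        raise ValueError("J_tox must be non-negative")
    return math.exp(-J_tox)


def fit_k_per_concentration(
    data: SliceViabilityDataset, method: str = "loglinear", details: bool = False
):
    """Per-concentration decay rate: map concentration -> (k, r_squared).

    Replicates are pooled. ``"loglinear"`` (default) is the zero-intercept
    least-squares fit of ln(viability) = -k t, anchoring N(t=0) at the
    control; ``"exponential"`` fits N = exp(-k t) by nonlinear least
    squares (differences only matter with noise). Non-positive viabilities
    cannot enter the log fit and are dropped with a warning.

    With ``details=True`` the values are (k, r_squared, var_k), where var_k
    is the sampling variance of the rate estimate from the log-fit
    residuals -- used to weight the downstream power-law regression.
    """
    from scipy.optimize import curve_fit

    out = {}
    for conc, grp in data.table.groupby("concentration_M"):
        t = grp["time_min"].to_numpy(dtype=float)
        v = grp["viability"].to_numpy(dtype=float)
        keep = v > 0
        if not keep.all():
            warnings.warn(
                f"C={conc} M: dropped {np.sum(~keep)} non-positive viability point(s)",
                stacklevel=2,
            )
        t, v = t[keep], v[keep]
        if np.unique(t).size < 2:
            raise ValueError(f"C={conc} M: need >= 2 exposure times with usable viability")
        ln_v = np.log(v)
        if method == "loglinear":
            k = -float(np.sum(t * ln_v) / np.sum(t * t))
        elif method == "exponential":
            (k,), _ = curve_fit(lambda tt, kk: np.exp(-kk * tt), t, v, p0=[1e-3])
            k = float(k)
        else:
            raise ValueError(f"unknown method {method!r}")
        pred = np.exp(-k * t)
        ss_tot = float(np.sum((v - v.mean()) ** 2))
        r2 = 1.0 - float(np.sum((v - pred) ** 2)) / ss_tot if ss_tot > 0 else float("nan")
        resid = ln_v + k * t
        dof = max(t.size - 1, 1)
        var_k = float(np.sum(resid**2) / dof / np.sum(t * t))
        k = max(k, 0.0)
        out[float(conc)] = (k, r2, var_k) if details else (k, r2)
    return out


def fit_alpha_beta(rates: dict, weighted: bool = True) -> ToxicityParams:
    """Power-law fit of the toxicity rate: regression of ln k on ln C.

    ``rates`` maps concentration (mol/L) to k (1/min), or to (k, r2) /
    (k, r2, var_k) tuples as produced by :func:`fit_k_per_concentration`.
    Non-positive rates are excluded with a warning (a zero rate carries no
    log-scale information).

    When sampling variances are available and ``weighted`` is True, the
    regression is inverse-variance weighted on the log scale
    (w = k^2/var_k): rate estimates at low concentrations, where the decay
    over the assay window is comparable to assay noise, would otherwise
    dominate the error of the exponent.
    """
    C, k, w = [], [], []
    for c, val in rates.items():
        if isinstance(val, tuple):
            kk = val[0]
            var_k = val[2] if len(val) > 2 else None
        else:
            kk, var_k = float(val), None
        if kk <= 0:
            warnings.warn(f"C={c} M: non-positive rate excluded from power-law fit",
                          stacklevel=2)
            continue
        C.append(c)
        k.append(kk)
        w.append(kk**2 / var_k if (weighted and var_k and var_k > 0) else None)
    if len(C) < 2:
        raise ValueError("need >= 2 concentrations with positive rates")
    C, k = np.asarray(C), np.asarray(k)
    X = np.column_stack([np.log(C), np.ones_like(C)])
    y = np.log(k)
    if weighted and all(x is not None for x in w):
        W = np.asarray(w)
        slope, intercept = np.linalg.lstsq(X * W[:, None] ** 0.5, y * W**0.5, rcond=None)[0]
    else:
        slope, intercept = np.linalg.lstsq(X, y, rcond=None)[0]
    return ToxicityParams(alpha=float(slope), beta=float(np.exp(intercept)))


def fit_toxicity(data: SliceViabilityDataset, method: str = "loglinear") -> ToxicityParams:
    """Full pipeline: per-concentration rates (with variances) -> weighted power law."""
    return fit_alpha_beta(fit_k_per_concentration(data, method=method, details=True))


def characteristic_diffusion_time(half_thickness_m: float, D_m2_s: float) -> float:
    """Diffusive equilibration time t = l^2/(2D) for a slab of half-thickness l."""
    if D_m2_s <= 0:
        raise ValueError("diffusivity must be positive")
    if half_thickness_m < 0:
        raise ValueError("length must be non-negative")
    return half_thickness_m**2 / (2.0 * D_m2_s)
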