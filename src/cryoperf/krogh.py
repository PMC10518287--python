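"""Krogh-unit transport model: geometry, Kedem-Katchalsky fluxes, loading simulation.

One repeating unit is a hexagonal tissue prism (apothem ``r_k``) around a
central capillary (radius ``r_c``, length ``l_c``). Only part of the tissue
exchanges water osmotically; the osmotically active volume forms a smaller
hexagonal prism of apothem ``r_a``. Because the outer boundary of the unit
is fixed by symmetry, any change of active volume is accommodated by the
capillary lumen: tissue swelling narrows the capillary and raises vascular
resistance by Poiseuille's fourth-power law, tissue shrinkage widens it.

Water flux across the capillary membrane follows the Kedem-Katchalsky
equation (hydraulic conductivity ``L_p``, reflection coefficient ``sigma``).
Tissue CPA content relaxes toward the capillary concentration with a rate
set by the solute permeability ``omega`` over a fixed exchange area -- an
effective organ-level permeation model; the full mole-bookkeeping form with
solvent drag is available via ``SimSettings.solute_update``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid, solve_ivp

from .units import GAS_CONSTANT, ISOTONIC_OSMOLARITY, MIN_TO_S, MOLAR_TO_MOL_M3

HEX = 2.0 * math.sqrt(3.0)  # hexagon area = HEX * apothem^2


class OsmoticCollapseError(RuntimeError):
    """Tissue volume left the range representable by the unit geometry."""


@dataclass(frozen=True)
class KroghGeometry:
    """Dimensions of the repeating Krogh unit (SI metres).

    Parameters
    ----------
    r_c0
        Capillary radius under isotonic conditions.
    r_k
        Apothem of the hexagonal unit (half intercapillary distance).
    l_c
        Capillary length.
    r_a
        Apothem of the osmotically active volume; fitted per organ from the
        organ Boyle van't Hoff plot (see :mod:`cryoperf.bvh`).
    """

    r_c0: float = 3e-6
    r_k: float = 7.5e-6
    l_c: float = 55e-6
    r_a: float = 3.86e-6

    def __post_init__(self) -> None:
        if not (0 < self.r_c0 < self.r_a <= self.r_k):
            raise ValueError(
                f"need 0 < r_c0 < r_a <= r_k, got r_c0={self.r_c0}, "
                f"r_a={self.r_a}, r_k={self.r_k}"
            )
        if self.l_c <= 0:
            raise ValueError("l_c must be positive")
        if self.V0 <= 0:
            raise ValueError("initial active volume is not positive")

    @property
    def V0(self) -> float:
        """Initial (isotonic) active volume, m^3."""
        return self.l_c * (HEX * self.r_a**2 - math.pi * self.r_c0**2)

    @property
    def V_max(self) -> float:
        """Active volume at which the capillary lumen closes entirely."""
        return self.l_c * HEX * self.r_a**2


@dataclass(frozen=True)
class MembraneParams:
    """Effective membrane transport constants of the whole organ.

    ``L_p`` [m^3/(N s)] scales water flux, ``omega`` [mol/(N s)] scales CPA
    flux, and ``sigma`` (dimensionless, 0..1) is the reflection coefficient:
    the degree to which the membrane rejects the permeant CPA (1 =
    impermeable, 0 = freely permeating).
    """

    L_p: float = 1.5e-14
    omega: float = 7.0e-13
    sigma: float = 0.10

    def __post_init__(self) -> None:
        if self.L_p <= 0:
            raise ValueError("L_p must be positive")
        if self.omega < 0:
            raise ValueError("omega must be non-negative")
        if not 0 <= self.sigma <= 1:
            raise ValueError("sigma must be in [0, 1]")


@dataclass(frozen=True)
class SimSettings:
    """Numerical and environmental settings for the forward model.

    ``hydraulic_dP`` is the transmembrane hydraulic pressure P_f - P_t (Pa);
    at molar CPA the osmotic term (~2.3 MPa per M) dwarfs perfusion
    pressures (40 mmHg ~ 5.3 kPa), so it defaults to zero.

    ``surface_mode`` selects the membrane exchange area: ``"fixed"`` uses
    the isotonic capillary radius throughout, ``"instantaneous"`` tracks
    r_c(t). ``solute_update`` selects the tissue CPA balance:
    ``"concentration"`` relaxes the tissue concentration over the fixed
    isotonic active volume (diffusive term only), ``"moles"`` integrates the
    full Kedem-Katchalsky solute flux (diffusive + solvent drag) as an
    amount, with concentration derived from the instantaneous volume.
    """

    temperature: float = 277.15  # K (4 C)
    gas_constant: float = GAS_CONSTANT
    hydraulic_dP: float = 0.0  # Pa
    surface_mode: Literal["fixed", "instantaneous"] = "fixed"
    solute_update: Literal["concentration", "moles"] = "concentration"
    rel_tol: float = 1e-8
    abs_tol: float = 1e-12
    output_dt: float = 1.0  # s

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.output_dt <= 0:
            raise ValueError("output_dt must be positive")
        if self.surface_mode not in ("fixed", "instantaneous"):
            raise ValueError(f"unknown surface_mode {self.surface_mode!r}")
        if self.solute_update not in ("concentration", "moles"):
            raise ValueError(f"unknown solute_update {self.solute_update!r}")


@dataclass(frozen=True)
class BoundaryState:
    """Arterial (capillary fluid) boundary condition at one instant."""

    C_cpa_f: float  # mol/m^3
    C_is_f: float  # mol/m^3
    pressure: float = 0.0  # Pa, recorded; inert unless hydraulic_dP set
    viscosity_ratio: float = 1.0  # mu(t)/mu_baseline

    def __post_init__(self) -> None:
        if self.C_cpa_f < 0 or self.C_is_f < 0:
            raise ValueError("concentrations must be non-negative")
        if self.viscosity_ratio <= 0:
            raise ValueError("viscosity_ratio must be positive")


@dataclass(frozen=True)
class TissueState:
    """Lumped tissue compartment: active volume and solute amounts."""

    V: float  # m^3
    n_cpa: float  # mol
    n_is: float  # mol, constant over any run

    def __post_init__(self) -> None:
        if not np.isfinite(self.V) or self.V <= 0:
            raise ValueError(f"active volume must be positive and finite, got {self.V}")
        if not np.isfinite(self.n_cpa) or self.n_cpa < 0:
            raise ValueError("n_cpa must be non-negative and finite")

    @property
    def C_cpa_t(self) -> float:
        return self.n_cpa / self.V

    @property
    def C_is_t(self) -> float:
        return self.n_is / self.V


def capillary_radius(V: float | np.ndarray, geom: KroghGeometry) -> float | np.ndarray:
    """Capillary radius for a given active volume.

    The unit's outer hexagon is fixed, so volume lost by the active tissue
    is gained by the lumen: r_c = sqrt((2*sqrt(3)*r_a^2 - V/l_c)/pi).
    """
    arg = (HEX * geom.r_a**2 - np.asarray(V) / geom.l_c) / math.pi
    if np.any(np.asarray(V) <= 0) or np.any(arg <= 0):
        raise OsmoticCollapseError(
            "active volume outside (0, V_max); unit geometry collapsed"
        )
    r = np.sqrt(arg)
    return float(r) if np.isscalar(V) or np.ndim(V) == 0 else r


def structural_resistance_norm(r_c: float | np.ndarray, geom: KroghGeometry) -> float | np.ndarray:
    """Vascular structural resistance normalized to the isotonic baseline.

    Poiseuille flow in n parallel units gives R = 8 l_c / (n pi r_c^4);
    normalizing by the isotonic value cancels n and l_c, leaving
    (r_c0/r_c)^4.
    """
    r_c = np.asarray(r_c, dtype=float)
    if np.any(r_c <= 0):
        raise ValueError("capillary radius must be positive")
    out = (geom.r_c0 / r_c) ** 4
    return float(out) if out.ndim == 0 else out


def perfusion_resistance_norm(
    R_norm: float | np.ndarray, viscosity_ratio: float | np.ndarray
) -> float | np.ndarray:
    """Perfusion (pressure/flow) resistance: structural resistance times viscosity."""
    R_norm = np.asarray(R_norm, dtype=float)
    visc = np.asarray(viscosity_ratio, dtype=float)
    if np.any(R_norm <= 0) or np.any(visc <= 0):
        raise ValueError("R_norm and viscosity_ratio must be positive")
    out = visc * R_norm
    return float(out) if out.ndim == 0 else out


def _surface_area(V: float, geom: KroghGeometry, settings: SimSettings) -> float:
    r_c = geom.r_c0 if settings.surface_mode == "fixed" else capillary_radius(V, geom)
    return 2.0 * math.pi * r_c * geom.l_c


def kk_fluxes(
    tissue: TissueState,
    boundary: BoundaryState,
    mem: MembraneParams,
    geom: KroghGeometry,
    settings: SimSettings = SimSettings(),
) -> tuple[float, float]:
    """Kedem-Katchalsky water and CPA fluxes across the capillary membrane.

    Returns ``(J_v, J_cpa)`` in (m^3/s, mol/s), positive into the tissue:

    J_v   = S L_p [dP - R_g T (C_is,f - C_is,t + sigma (C_cpa,f - C_cpa,t))]
    J_cpa = S omega R_g T (C_cpa,f - C_cpa,t)
            + J_v (1 - sigma) (C_cpa,f + C_cpa,t)/2
    """
    RT = settings.gas_constant * settings.temperature
    S = _surface_area(tissue.V, geom, settings)
    dC_is = boundary.C_is_f - tissue.C_is_t
    dC_cpa = boundary.C_cpa_f - tissue.C_cpa_t
    J_v = S * mem.L_p * (settings.hydraulic_dP - RT * (dC_is + mem.sigma * dC_cpa))
    J_cpa = S * mem.omega * RT * dC_cpa + J_v * (1.0 - mem.sigma) * (
        boundary.C_cpa_f + tissue.C_cpa_t
    ) / 2.0
    if not (np.isfinite(J_v) and np.isfinite(J_cpa)):
        raise ValueError("non-finite flux; check state and boundary")
    return J_v, J_cpa


@dataclass
class SimulationResult:
    """Dense time series of the tissue state during a loading run.

    Arrays are aligned on ``time_min``. ``R_norm`` is the structural
    resistance relative to the isotonic start; ``Rp_norm`` is the perfusion
    resistance relative to the end-of-flush (carrier-equilibrated) baseline,
    which is how experimental traces are normalized. ``J_tox_cum`` is the
    running toxicity cost (dimensionless; minutes x molar units).
    """

    time_min: np.ndarray
    C_art_M: np.ndarray
    V: np.ndarray  # m^3
    C_tissue_M: np.ndarray
    viscosity_ratio: np.ndarray
    geom: KroghGeometry
    baseline_index: int  # end-of-flush sample used as normalization baseline
    J_tox_cum: np.ndarray = field(default=None)  # filled by simulate_loading
    full_strength_start_min: float | None = None
    full_strength_duration_min: float | None = None
    target_reached: bool = True

    @property
    def V0(self) -> float:
        return self.geom.V0

    @property
    def v_frac(self) -> np.ndarray:
        """Active volume relative to the isotonic volume V0."""
        return self.V / self.V0

    @property
    def V_baseline(self) -> float:
        return float(self.V[self.baseline_index])

    @property
    def v_frac_baseline(self) -> np.ndarray:
        """Active volume relative to the end-of-flush baseline."""
        return self.V / self.V_baseline

    @property
    def rc(self) -> np.ndarray:
        return capillary_radius(self.V, self.geom)

    @property
    def R_norm(self) -> np.ndarray:
        return structural_resistance_norm(self.rc, self.geom)

    @property
    def Rp_norm(self) -> np.ndarray:
        rc = self.rc
        R_rel_baseline = (rc[self.baseline_index] / rc) ** 4
        return perfusion_resistance_norm(R_rel_baseline, self.viscosity_ratio)

    @property
    def final_C_tissue_M(self) -> float:
        return float(self.C_tissue_M[-1])

    @property
    def J_tox(self) -> float:
        return float(self.J_tox_cum[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.time_min,
                "C_art_M": self.C_art_M,
                "V_frac": self.v_frac,
                "C_tissue_M": self.C_tissue_M,
                "rc_um": self.rc * 1e6,
                "R_norm": self.R_norm,
                "Rp_norm": self.Rp_norm,
                "Jtox_cum": self.J_tox_cum,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _integrate_phase(
    rhs: Callable,
    t_span: tuple[float, float],
    y0: np.ndarray,
    settings: SimSettings,
    geom: KroghGeometry,
    events=None,
):
    """One protocol segment; terminal events guard geometric collapse."""

    def v_floor(t, y):
        return y[0] - 1e-4 * geom.V0

    def v_ceil(t, y):
        return geom.V_max * (1 - 1e-9) - y[0]

    v_floor.terminal = v_ceil.terminal = True
    evs = [v_floor, v_ceil] + (events or [])
    sol = solve_ivp(
        rhs,
        t_span,
        y0,
        method="LSODA",
        rtol=settings.rel_tol,
        atol=[geom.V0 * settings.abs_tol, max(settings.abs_tol, 1e-9)],
        dense_output=True,
        max_step=60.0,
        events=evs,
    )
    if not sol.success:
        raise RuntimeError(f"integrator failed: {sol.message}")
    if len(sol.t_events[0]) or len(sol.t_events[1]):
        raise OsmoticCollapseError(
            "active volume collapsed during integration (V outside (0, V_max))"
        )
    return sol


def simulate_loading(
    protocol,
    geom: KroghGeometry = KroghGeometry(),
    mem: MembraneParams = MembraneParams(),
    tox=None,
    settings: SimSettings = SimSettings(),
    target_conc_M: float | None = None,
) -> SimulationResult:
    """Integrate a CPA loading protocol from the isotonic initial state.

    The tissue starts isotonic (V = V0, impermeant osmolarity 290 mol/m^3,
    no CPA). State variables are the active volume V (water balance, KK
    water flux) and the tissue CPA content, updated per
    ``settings.solute_update``. The impermeant amount n_is is constant.

    If ``protocol.full_strength_duration`` is ``"auto"``, the full-strength
    hold is terminated by event detection when the tissue concentration
    first reaches ``target_conc_M`` (capped at ``protocol.hold_cap_min``);
    if the cap is hit first the result is flagged ``target_reached=False``.

    ``tox`` (ToxicityParams) fills the cumulative toxicity cost on the
    output grid; if None, J_tox_cum is all zeros.
    """
    from .toxicity import toxicity_rate  # local import; no cycle at module load

    M_iso = ISOTONIC_OSMOLARITY
    V0 = geom.V0
    n_is = M_iso * V0
    RT = settings.gas_constant * settings.temperature
    sigma, L_p, omega = mem.sigma, mem.L_p, mem.omega
    conc_mode = settings.solute_update == "concentration"
    S_fixed = 2.0 * math.pi * geom.r_c0 * geom.l_c
    instantaneous = settings.surface_mode == "instantaneous"
    hex_ra2 = HEX * geom.r_a**2

    C_is_f = protocol.carrier_osmolarity  # mol/m^3, constant carrier background
    c_art = protocol.arterial_concentration_si  # t_s -> mol/m^3

    def rhs(t, y):
        V, x = y
        C_t = x if conc_mode else x / V
        C_f = c_art(t)
        if instantaneous:
            S = 2.0 * math.pi * math.sqrt(max((hex_ra2 - V / geom.l_c) / math.pi, 0.0)) * geom.l_c
        else:
            S = S_fixed
        J_v = S * L_p * (settings.hydraulic_dP - RT * (C_is_f - n_is / V + sigma * (C_f - C_t)))
        diffusive = S * omega * RT * (C_f - C_t)
        if conc_mode:
            dx = diffusive / V0
        else:
            dx = diffusive + J_v * (1.0 - sigma) * (C_f + C_t) / 2.0
        return (J_v, dx)

    # --- segment breakpoints (seconds) ---
    t_flush = protocol.flush_duration * MIN_TO_S
    t_ramp = t_flush + protocol.ramp_duration * MIN_TO_S
    t_plat = t_ramp + protocol.plateau_duration * MIN_TO_S
    auto = protocol.full_strength_duration == "auto"
    if auto and target_conc_M is None:
        raise ValueError("auto full-strength duration requires target_conc_M")

    y = np.array([V0, 0.0])
    segments = []  # (sol, t0, t1)
    for t0, t1 in [(0.0, t_flush), (t_flush, t_ramp), (t_ramp, t_plat)]:
        if t1 > t0:
            sol = _integrate_phase(rhs, (t0, t1), y, settings, geom)
            segments.append((sol, t0, t1))
            y = sol.y[:, -1]

    target_reached = True
    if auto:
        cap = t_plat + protocol.hold_cap_min * MIN_TO_S
        tgt = target_conc_M * MOLAR_TO_MOL_M3
        if (y[1] if conc_mode else y[1] / y[0]) >= tgt:
            t_end = t_plat  # target already exceeded at the step
        else:
            def hit(t, yy):
                C = yy[1] if conc_mode else yy[1] / yy[0]
                return C - tgt

            hit.terminal = True
            hit.direction = 1
            sol = _integrate_phase(rhs, (t_plat, cap), y, settings, geom, events=[hit])
            if len(sol.t_events[2]):
                t_end = float(sol.t_events[2][0])
            else:
                t_end = cap
                target_reached = False
            segments.append((sol, t_plat, t_end))
    else:
        t_end = t_plat + protocol.full_strength_duration * MIN_TO_S
        if t_end > t_plat:
            sol = _integrate_phase(rhs, (t_plat, t_end), y, settings, geom)
            segments.append((sol, t_plat, t_end))

    # --- dense output on the common grid ---
    tt = np.arange(0.0, t_end + 1e-9, settings.output_dt)
    if tt[-1] < t_end - 1e-9:
        tt = np.append(tt, t_end)  # keep the exact event/end time on the grid
    Y = np.empty((2, tt.size))
    for sol, t0, t1 in segments:
        m = (tt >= t0) & (tt <= t1)
        if m.any():
            Y[:, m] = sol.sol(tt[m])
    V = Y[0]
    C_t = Y[1] if conc_mode else Y[1] / V
    C_art = np.array([c_art(t) for t in tt])

    time_min = tt / MIN_TO_S
    C_tissue_M = C_t / MOLAR_TO_MOL_M3
    visc = np.array([protocol.viscosity_ratio(tm) for tm in time_min])
    baseline_index = int(np.searchsorted(tt, t_flush)) if t_flush > 0 else 0
    baseline_index = min(baseline_index, tt.size - 1)

    if tox is not None:
        rate = toxicity_rate(np.clip(C_tissue_M, 0.0, None), tox)  # 1/min
        J_cum = np.concatenate([[0.0], cumulative_trapezoid(rate, time_min)])
    else:
        J_cum = np.zeros_like(tt)

    hold_start = t_plat / MIN_TO_S
    return SimulationResult(
        time_min=time_min,
        C_art_M=C_art / MOLAR_TO_MOL_M3,
        V=V,
        C_tissue_M=C_tissue_M,
        viscosity_ratio=visc,
        geom=geom,
        baseline_index=baseline_index,
        J_tox_cum=J_cum,
        full_strength_start_min=hold_start,
        full_strength_duration_min=t_end / MIN_TO_S - hold_start,
        target_reached=target_reached,
    )
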