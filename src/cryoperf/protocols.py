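"""Ramp-hold-step loading protocols, osmotic feasibility, and grid optimization.

A loading protocol is: a carrier-only flush (baseline), a linear arterial
CPA ramp, a constant plateau, then a step to full strength held either for
a fixed time or ("auto") until the tissue concentration reaches a
vitrifiable target. Feasibility is judged on the osmotic volume excursion:
the active volume (relative to the end-of-flush baseline) must never fall
below a hard floor (45%) and may spend only a limited time (25 min) below
the osmotic-stress floor (73%).

The optimizer sweeps (ramp rate, ramp duration, plateau duration)
exhaustively, excludes infeasible points, and returns the protocol with the
smallest cumulative toxicity cost.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Union

import numpy as np
import pandas as pd

from .krogh import KroghGeometry, MembraneParams, SimSettings, SimulationResult, simulate_loading
from .toxicity import ToxicityParams
from .units import MOLAR_TO_MOL_M3


@dataclass(frozen=True)
class LoadingProtocol:
    """Piecewise arterial boundary for ramp-hold-step CPA loading.

    Times are minutes, the ramp rate is mM/min, concentrations molar. The
    plateau concentration is implied: ramp_rate * ramp_duration / 1000.
    Pressure is recorded for provenance (40 mmHg during loading, 60 mmHg at
    the full-strength step to maintain flow against viscosity) but does not
    enter the transport model by default. ``viscosity_slope`` sets the
    displayed perfusion-resistance viscosity ratio, 1 + slope * C_art [M].
    """

    ramp_rate: float  # mM/min
    ramp_duration: float  # min
    plateau_duration: float  # min
    flush_duration: float = 20.0  # min
    full_strength_conc: float = 8.4  # M
    full_strength_duration: Union[float, str] = "auto"  # min or "auto"
    hold_cap_min: float = 60.0
    pressure_main: float = 40.0  # mmHg
    pressure_full: float = 60.0  # mmHg
    carrier_osmolarity: float = 330.0  # mol/m^3 (LM5-XZ)
    viscosity_slope: float = 0.15  # per molar

    def __post_init__(self) -> None:
        for name in ("ramp_rate", "ramp_duration", "plateau_duration", "flush_duration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.full_strength_conc <= 0 or self.carrier_osmolarity <= 0:
            raise ValueError("concentrations must be positive")
        if self.plateau_conc > self.full_strength_conc + 1e-12:
            raise ValueError(
                f"plateau concentration {self.plateau_conc:.3g} M exceeds "
                f"full-strength {self.full_strength_conc} M"
            )
        if self.full_strength_duration != "auto" and self.full_strength_duration < 0:
            raise ValueError("full_strength_duration must be 'auto' or >= 0")

    @property
    def plateau_conc(self) -> float:
        """Arterial concentration held during the plateau, M."""
        return self.ramp_rate * self.ramp_duration / 1000.0

    @property
    def step_time_min(self) -> float:
        return self.flush_duration + self.ramp_duration + self.plateau_duration

    def arterial_concentration(self, t_min: float) -> float:
        """Arterial CPA concentration (M) at protocol time t (min from flush start)."""
        if t_min < self.flush_duration:
            return 0.0
        if t_min < self.flush_duration + self.ramp_duration:
            return self.ramp_rate * (t_min - self.flush_duration) / 1000.0
        if t_min < self.step_time_min:
            return self.plateau_conc
        return self.full_strength_conc

    def arterial_concentration_si(self, t_s: float) -> float:
        return self.arterial_concentration(t_s / 60.0) * MOLAR_TO_MOL_M3

    def pressure_mmHg(self, t_min: float) -> float:
        return self.pressure_full if t_min >= self.step_time_min else self.pressure_main

    def viscosity_ratio(self, t_min: float) -> float:
        return 1.0 + self.viscosity_slope * self.arterial_concentration(t_min)


def build_protocol(
    ramp_rate: float, ramp_duration: float, plateau_duration: float, **overrides
) -> LoadingProtocol:
    """Construct a ramp-hold-step protocol; overrides pass through to LoadingProtocol."""
    return LoadingProtocol(
        ramp_rate=ramp_rate,
        ramp_duration=ramp_duration,
        plateau_duration=plateau_duration,
        **overrides,
    )


def existing_protocol(**overrides) -> LoadingProtocol:
    """The empirically developed reference protocol: 50 mM/min to 5 M over
    100 min, 10 min plateau, 25 min at full strength."""
    kw = dict(full_strength_duration=25.0)
    kw.update(overrides)
    return build_protocol(50.0, 100.0, 10.0, **kw)


def optimized_protocol(**overrides) -> LoadingProtocol:
    """The model-optimized protocol: 62 mM/min for 80 min, 5 min plateau,
    full-strength hold auto-terminated at the vitrifiable target."""
    return build_protocol(62.0, 80.0, 5.0, **overrides)


@dataclass(frozen=True)
class OsmoticConstraints:
    """Volume-excursion limits relative to the end-of-flush baseline."""

    hard_floor: float = 0.45
    stress_floor: float = 0.73
    stress_time_max: float = 25.0  # min, cumulative
    contiguous: bool = False  # if True, limit the longest contiguous stretch instead

    def __post_init__(self) -> None:
        if not 0 < self.hard_floor < self.stress_floor < 1:
            raise ValueError("need 0 < hard_floor < stress_floor < 1")
        if self.stress_time_max < 0:
            raise ValueError("stress_time_max must be non-negative")


def check_osmotic(
    sim: SimulationResult, constraints: OsmoticConstraints = OsmoticConstraints()
) -> tuple[bool, float, float]:
    """Osmotic feasibility of a simulated run.

    Returns (feasible, min_Vfrac, time_below_stress_floor_min), with volume
    fractions relative to the end-of-flush baseline.
    """
    v = sim.v_frac_baseline
    t = sim.time_min
    min_v = float(v.min())
    below = v < constraints.stress_floor
    # integrate indicator on the (possibly non-uniform) output grid
    dt = np.diff(t)
    seg = 0.5 * (below[:-1].astype(float) + below[1:].astype(float)) * dt
    if constraints.contiguous:
        stress_time = 0.0
        run = 0.0
        for s, b0, b1 in zip(seg, below[:-1], below[1:]):
            if b0 or b1:
                run += s
                stress_time = max(stress_time, run)
            else:
                run = 0.0
    else:
        stress_time = float(seg.sum())
    feasible = min_v >= constraints.hard_floor and stress_time <= constraints.stress_time_max
    return feasible, min_v, float(stress_time)


@dataclass(frozen=True)
class OptimizationGrid:
    """Exhaustive sweep design over ramp-hold-step parameters."""

    ramp_rates: np.ndarray = field(
        default_factory=lambda: np.arange(40.0, 70.0 + 0.5, 1.0)
    )  # mM/min
    ramp_durations: np.ndarray = field(
        default_factory=lambda: np.arange(70.0, 120.0 + 0.5, 5.0)
    )  # min
    plateau_durations: np.ndarray = field(
        default_factory=lambda: np.arange(4.0, 20.0 + 0.5, 1.0)
    )  # min
    plateau_conc_bounds: tuple = (3.0, 7.0)  # M

    def __post_init__(self) -> None:
        for name in ("ramp_rates", "ramp_durations", "plateau_durations"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.size == 0:
                raise ValueError(f"{name} is empty")

    def points(self):
        return itertools.product(self.ramp_rates, self.ramp_durations, self.plateau_durations)

    def __len__(self) -> int:
        return self.ramp_rates.size * self.ramp_durations.size * self.plateau_durations.size


@dataclass
class OptimizationResult:
    """Full sweep records plus the feasible toxicity-cost minimizer."""

    records: pd.DataFrame
    best: LoadingProtocol
    best_J_tox: float
    target_conc_M: float

    @property
    def per_rate_minimum(self) -> pd.DataFrame:
        """Minimum feasible J_tox at each ramp rate (the rate-sweep curve)."""
        feas = self.records[self.records["feasible"]]
        idx = feas.groupby("ramp_rate_mM_min")["Jtox"].idxmin()
        return feas.loc[idx].reset_index(drop=True)


def auto_full_strength_duration(sim: SimulationResult) -> float:
    """Duration of the auto-terminated full-strength hold of a simulated run."""
    if sim.full_strength_duration_min is None:
        raise ValueError("run has no full-strength phase")
    return sim.full_strength_duration_min


def optimize_protocol(
    grid: OptimizationGrid = OptimizationGrid(),
    geom: KroghGeometry = KroghGeometry(),
    mem: MembraneParams = MembraneParams(),
    tox: ToxicityParams = ToxicityParams(),
    constraints: OsmoticConstraints = OsmoticConstraints(),
    target_conc_M: float | None = None,
    settings: SimSettings = SimSettings(),
    protocol_defaults: LoadingProtocol | None = None,
) -> OptimizationResult:
    """Exhaustive constrained minimization of J_tox over the protocol grid.

    Every grid point is simulated with an auto-terminated full-strength
    hold. Points are infeasible if the plateau concentration leaves the
    allowed band, the osmotic constraints are violated, or the tissue never
    reaches the target. ``target_conc_M`` defaults to the simulated
    endpoint of the existing protocol, so the vitrifiable target is
    self-consistent with the model in use. Deterministic; ties are broken
    by shortest total protocol, then lowest ramp rate.
    """
    if target_conc_M is None:
        ref = simulate_loading(existing_protocol(), geom, mem, tox, settings)
        target_conc_M = ref.final_C_tissue_M

    base = protocol_defaults if protocol_defaults is not None else LoadingProtocol(0, 0, 0)
    rows = []
    for rate, dur, plat in grid.points():
        rec = {
            "ramp_rate_mM_min": rate,
            "ramp_dur_min": dur,
            "plateau_dur_min": plat,
            "plateau_conc_M": rate * dur / 1000.0,
            "feasible": False,
            "Jtox": np.nan,
            "full_strength_min": np.nan,
            "min_Vfrac": np.nan,
            "stress_time_min": np.nan,
            "reason": "",
        }
        lo, hi = grid.plateau_conc_bounds
        if not lo <= rec["plateau_conc_M"] <= hi:
            rec["reason"] = "plateau_conc_out_of_bounds"
            rows.append(rec)
            continue
        protocol = replace(
            base,
            ramp_rate=rate,
            ramp_duration=dur,
            plateau_duration=plat,
            full_strength_duration="auto",
        )
        sim = simulate_loading(protocol, geom, mem, tox, settings, target_conc_M=target_conc_M)
        ok, min_v, stress = check_osmotic(sim, constraints)
        rec.update(
            Jtox=sim.J_tox,
            full_strength_min=sim.full_strength_duration_min,
            min_Vfrac=min_v,
            stress_time_min=stress,
        )
        if not sim.target_reached:
            rec["reason"] = "target_unreachable"
        elif not ok:
            rec["reason"] = "osmotic_violation"
        else:
            rec["feasible"] = True
        rows.append(rec)

    records = pd.DataFrame(rows)
    feas = records[records["feasible"]]
    if feas.empty:
        raise RuntimeError("no feasible protocol in the grid")
    feas = feas.assign(
        total_min=feas["ramp_dur_min"] + feas["plateau_dur_min"] + feas["full_strength_min"]
    )
    feas = feas.sort_values(
        ["Jtox", "total_min", "ramp_rate_mM_min"], kind="mergesort"
    )
    top = feas.iloc[0]
    best = replace(
        base,
        ramp_rate=float(top["ramp_rate_mM_min"]),
        ramp_duration=float(top["ramp_dur_min"]),
        plateau_duration=float(top["plateau_dur_min"]),
        full_strength_duration="auto",
    )
    return OptimizationResult(
        records=records,
        best=best,
        best_J_tox=float(top["Jtox"]),
        target_conc_M=float(target_conc_M),
    )
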