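"""Synthetic experiment generator: every fitting stage testable without a rig.

Generates the three experiment shapes the estimation pipeline consumes,
from the forward models plus controlled noise:

* solution-switch resistance traces (impermeant or CPA challenge) for the
  L_p and (omega, sigma) fits -- multiplicative Gaussian noise, like an
  instrument CV;
* stepped-osmolarity steady resistance plateaus for the organ Boyle van't
  Hoff fit of r_a;
* slice-viability tables (concentration x exposure time x replicate) for
  the toxicity power-law fit -- additive Gaussian noise on the viability
  fraction, clipped at zero.

All generators are pure functions of (config, seed): the same seed gives
byte-identical output. Defaults mirror the perfusion and slice-assay
designs the model parameters were originally measured with: LM5 carrier
(283 mOsm) with +150/+300 mM lactose steps, a 15-min impermeant challenge,
a 30-min 25%-strength CPA challenge, and slices at {2.1, 4.2, 6.3, 8.4} M
for {15, 30, 45, 60, 90, 120} min with n = 4 replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bvh import BvhDataset, steady_resistance_model
from .fitting import PerfusionTrace, Solution, simulate_switch
from .krogh import KroghGeometry, MembraneParams, SimSettings
from .toxicity import SliceViabilityDataset, ToxicityParams
from .units import ISOTONIC_OSMOLARITY

LM5_OSM = 283.0  # mol/m^3


@dataclass(frozen=True)
class SynthConfig:
    """True parameters, noise model, and sampling design for all generators."""

    geom: KroghGeometry = KroghGeometry()
    mem: MembraneParams = MembraneParams()
    tox: ToxicityParams = ToxicityParams()
    settings: SimSettings = SimSettings()
    seed: int = 0
    # noise
    resistance_cv: float = 0.02  # multiplicative, traces and plateaus
    viability_sd: float = 0.05  # additive, slice viability fractions
    # trace design
    trace_duration_impermeant: float = 15.0  # min
    trace_duration_cpa: float = 30.0  # min
    trace_dt: float = 0.1  # min
    carrier_osm: float = LM5_OSM
    lactose_step: float = 300.0  # mol/m^3 added for the impermeant challenge
    cpa_challenge_M: float = 2.1  # 25% of full strength
    cpa_viscosity_ratio: float = 1.3
    # slice-assay design
    slice_concentrations: tuple = (2.1, 4.2, 6.3, 8.4)  # M
    slice_times: tuple = (15.0, 30.0, 45.0, 60.0, 90.0, 120.0)  # min
    slice_replicates: int = 4

    def __post_init__(self) -> None:
        if self.resistance_cv < 0 or self.viability_sd < 0:
            raise ValueError("noise parameters must be non-negative")


def gen_resistance_trace(config: SynthConfig, challenge: str = "impermeant") -> PerfusionTrace:
    """Forward-simulated solution-switch trace with multiplicative noise.

    ``challenge="impermeant"`` emulates the L_p experiment (carrier ->
    carrier + lactose); ``"cpa"`` emulates the omega/sigma experiment
    (carrier -> quarter-strength CPA in carrier).
    """
    pre = Solution(C_is=config.carrier_osm)
    if challenge == "impermeant":
        post = Solution(C_is=config.carrier_osm + config.lactose_step)
        duration = config.trace_duration_impermeant
    elif challenge == "cpa":
        post = Solution(
            C_is=config.carrier_osm,
            C_cpa=config.cpa_challenge_M * 1000.0,
            viscosity_ratio=config.cpa_viscosity_ratio,
        )
        duration = config.trace_duration_cpa
    else:
        raise ValueError(f"unknown challenge {challenge!r}")
    t = np.arange(0.0, duration + 1e-9, config.trace_dt)
    _, rp = simulate_switch(
        pre, post, config.geom, config.mem, config.settings,
        duration_min=duration, eval_times_min=t,
    )
    rng = np.random.default_rng(config.seed)
    noisy = rp * (1.0 + config.resistance_cv * rng.standard_normal(rp.size))
    return PerfusionTrace(time_min=t, Rp_norm=np.clip(noisy, 1e-6, None), pre=pre, post=post)


def gen_bvh_plateaus(config: SynthConfig, osmolarities=None) -> BvhDataset:
    """Steady normalized resistances at several perfusate osmolarities.

    Equilibrium volumes follow the Boyle van't Hoff relation, mapped to
    resistance through the unit geometry, with multiplicative noise.
    Default osmolarities are the carrier and +150/+300 mM lactose steps.
    """
    if osmolarities is None:
        osmolarities = (config.carrier_osm, config.carrier_osm + 150.0,
                        config.carrier_osm + 300.0)
    M = np.asarray(osmolarities, dtype=float)
    if np.unique(M).size < 2:
        raise ValueError("need >= 2 distinct osmolarities")
    R = steady_resistance_model(M, config.geom, M_iso=ISOTONIC_OSMOLARITY)
    rng = np.random.default_rng(config.seed)
    R = R * (1.0 + config.resistance_cv * rng.standard_normal(R.size))
    return BvhDataset(osmolarities=M, R_norm=np.clip(R, 1e-9, None))


def gen_slice_viability(config: SynthConfig) -> SliceViabilityDataset:
    """Slice-assay table: viability = exp(-beta C^alpha t) * (1 + noise).

    Exposure at the final test concentration dominates the injury (the
    4-min loading steps are neglected, as in the assay's analysis); noise
    is Gaussian on the viability fraction and clipped at zero.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for C in config.slice_concentrations:
        k = config.tox.beta * C**config.tox.alpha
        for t in config.slice_times:
            true_v = np.exp(-k * t)
            eps = config.viability_sd * rng.standard_normal(config.slice_replicates)
            for rep, v in enumerate(np.clip(true_v * (1.0 + eps), 0.0, None)):
                rows.append(
                    {"concentration_M": C, "time_min": t, "replicate": rep, "viability": v}
                )
    return SliceViabilityDataset(table=pd.DataFrame(rows))
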