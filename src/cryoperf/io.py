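"""Readers and writers: perfusion traces, parameter files, simulation exports.

File conventions follow the experimental ones: delimited text with a header
row, times in minutes, concentrations in molar, pressures in mmHg.
Parameter files are JSON with unit-suffixed keys so a file is
self-describing; unknown keys are rejected to catch typos early.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np
import pandas as pd

from .fitting import PerfusionTrace, Solution
from .krogh import KroghGeometry, MembraneParams, SimSettings
from .toxicity import ToxicityParams

_GEOM_KEYS = {"r_c0_m": "r_c0", "r_k_m": "r_k", "l_c_m": "l_c", "r_a_m": "r_a"}
_MEM_KEYS = {"Lp_m3_per_N_s": "L_p", "omega_mol_per_N_s": "omega", "sigma": "sigma"}
_TOX_KEYS = {"alpha": "alpha", "beta_per_min_per_M_alpha": "beta",
             "temperature_label": "temperature_label"}
_SET_KEYS = {
    "temperature_K": "temperature",
    "hydraulic_dP_Pa": "hydraulic_dP",
    "surface_mode": "surface_mode",
    "solute_update": "solute_update",
    "rel_tol": "rel_tol",
    "abs_tol": "abs_tol",
    "output_dt_s": "output_dt",
}


def _build(section: dict, keymap: dict, cls, label: str):
    unknown = set(section) - set(keymap)
    if unknown:
        raise ValueError(f"unknown keys in {label!r} block: {sorted(unknown)}")
    return cls(**{keymap[k]: v for k, v in section.items()})


def read_params(path) -> dict:
    """Load a parameter file into model objects.

    Returns a dict with keys ``geometry``, ``membrane``, ``toxicity``,
    ``settings`` (missing blocks fall back to defaults) plus any
    ``provenance`` block passed through verbatim.
    """
    with open(path) as fh:
        raw = json.load(fh)
    known = {"geometry", "membrane", "toxicity", "settings", "provenance"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown top-level blocks: {sorted(unknown)}")
    out = {
        "geometry": _build(raw.get("geometry", {}), _GEOM_KEYS, KroghGeometry, "geometry"),
        "membrane": _build(raw.get("membrane", {}), _MEM_KEYS, MembraneParams, "membrane"),
        "toxicity": _build(raw.get("toxicity", {}), _TOX_KEYS, ToxicityParams, "toxicity"),
        "settings": _build(raw.get("settings", {}), _SET_KEYS, SimSettings, "settings"),
    }
    if "provenance" in raw:
        out["provenance"] = raw["provenance"]
    return out


def write_params(path, geometry: KroghGeometry, membrane: MembraneParams,
                 toxicity: ToxicityParams, settings: SimSettings = SimSettings(),
                 provenance: dict | None = None) -> None:
    """Write model objects to a unit-suffixed JSON parameter file."""
    inv = lambda keymap, obj: {k: getattr(obj, v) for k, v in keymap.items()}
    doc = {
        "geometry": inv(_GEOM_KEYS, geometry),
        "membrane": inv(_MEM_KEYS, membrane),
        "toxicity": inv(_TOX_KEYS, toxicity),
        "settings": inv(_SET_KEYS, settings),
    }
    if provenance:
        doc["provenance"] = provenance
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def default_params() -> dict:
    """The packaged reference parameter set (rat kidney, VMP at 4 C)."""
    with resources.files("cryoperf").joinpath("data/defaults.json").open() as fh:
        raw = json.load(fh)
    out = {
        "geometry": _build(raw["geometry"], _GEOM_KEYS, KroghGeometry, "geometry"),
        "membrane": _build(raw["membrane"], _MEM_KEYS, MembraneParams, "membrane"),
        "toxicity": _build(raw["toxicity"], _TOX_KEYS, ToxicityParams, "toxicity"),
        "settings": _build(raw["settings"], _SET_KEYS, SimSettings, "settings"),
        "provenance": raw.get("provenance", {}),
    }
    return out


def read_trace(
    path,
    pre: Solution,
    post: Solution,
    baseline_window_min: float | None = None,
    pressure_mmHg: float = 40.0,
) -> PerfusionTrace:
    """Read a perfusion trace from delimited text.

    Accepts either columns (time_min, Rp_norm), or (time_min,
    pressure_mmHg, flow_mL_min) from which Rp = P/Q is computed and then
    normalized so that the baseline window (samples with t < 0, or the
    first ``baseline_window_min`` minutes if given) has mean 1.
    """
    df = pd.read_csv(path)
    if "time_min" not in df.columns:
        raise ValueError("missing required column 'time_min'")
    t = df["time_min"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time_min must be strictly increasing")
    if "Rp_norm" in df.columns:
        rp = df["Rp_norm"].to_numpy(dtype=float)
    elif {"pressure_mmHg", "flow_mL_min"} <= set(df.columns):
        q = df["flow_mL_min"].to_numpy(dtype=float)
        if np.any(q <= 0):
            raise ValueError("flow must be positive")
        rp = df["pressure_mmHg"].to_numpy(dtype=float) / q
        base = t < 0 if baseline_window_min is None else t <= t[0] + baseline_window_min
        if not base.any():
            raise ValueError("no baseline samples to normalize against")
        rp = rp / rp[base].mean()
    else:
        raise ValueError(
            "need column 'Rp_norm', or 'pressure_mmHg' and 'flow_mL_min'"
        )
    return PerfusionTrace(time_min=t, Rp_norm=rp, pre=pre, post=post,
                          pressure_mmHg=pressure_mmHg)


def write_trace(path, trace: PerfusionTrace) -> None:
    pd.DataFrame({"time_min": trace.time_min, "Rp_norm": trace.Rp_norm}).to_csv(
        path, index=False
    )
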