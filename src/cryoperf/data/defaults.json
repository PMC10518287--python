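{
  "geometry": {
    "r_c0_m": 3e-06,
    "r_k_m": 7.5e-06,
    "l_c_m": 5.5e-05,
    "r_a_m": 3.86e-06
  },
  "membrane": {
    "Lp_m3_per_N_s": 1.5e-14,
    "omega_mol_per_N_s": 7.0e-13,
    "sigma": 0.10
  },
  "toxicity": {
    "alpha": 3.12,
    "beta_per_min_per_M_alpha": 9.39e-06,
    "temperature_label": "4C"
  },
  "settings": {
    "temperature_K": 277.15,
    "hydraulic_dP_Pa": 0.0,
    "surface_mode": "fixed",
    "solute_update": "concentration",
    "rel_tol": 1e-08,
    "abs_tol": 1e-12,
    "output_dt_s": 1.0
  },
  "provenance": {
    "note": "Rat-kidney VMP loading reference set: geometry from reported capillary dimensions; membrane and toxicity constants are perfusion- and slice-assay-fitted means at 4 C."
  }
}
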