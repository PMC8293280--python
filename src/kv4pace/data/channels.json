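{
  "_comment": "Voltage-gated conductance defaults for the SNc dopaminergic neuron model. Units: v50/e_rev in mV, slope_k in mV (signed), gmax in pS/um^2, time constants in ms, calcium in mM. A gate exponent of 0 means the gate is absent. Region order for gmax: soma+dendrites (includes axon_start), AIS, axon.",
  "channels": {
    "Na": {
      "m_gate": {"v50": -28.0, "slope_k": 8.0, "exponent": 3},
      "h_gate": {"v50": -50.0, "slope_k": -10.0, "exponent": 1},
      "e_rev": 60.0,
      "tau_m": {"rule_id": "na_m", "params": {}},
      "tau_h": {"rule_id": "na_h", "params": {}},
      "gmax": {"soma_dend": 75.0, "AIS": 4000.0, "axon": 400.0}
    },
    "KDR": {
      "m_gate": {"v50": -30.0, "slope_k": 9.0, "exponent": 4},
      "h_gate": {"v50": 0.0, "slope_k": 1.0, "exponent": 0},
      "e_rev": -90.0,
      "tau_m": {"rule_id": "kdr_m", "params": {}},
      "tau_h": {"rule_id": "constant", "params": {"value": 1.0}},
      "gmax": {"soma_dend": 150.0, "AIS": 4000.0, "axon": 400.0}
    },
    "A": {
      "_comment": "Inactivation v50 is coupled to I_H activation v50 (0.814*v50_H + 3.36); activation v50 = inactivation v50 + 50 mV; tau_m = tau_h/50. Grid ranges: gmax 15-150, tau_h 15-150 ms, induced v50_inact about -78 to -62 mV.",
      "m_gate": {"v50": -19.9, "slope_k": 7.0, "exponent": 1},
      "h_gate": {"v50": -69.9, "slope_k": -7.0, "exponent": 1},
      "e_rev": -90.0,
      "tau_m": {"rule_id": "ia_linked", "params": {"tau_h": 82.5}},
      "tau_h": {"rule_id": "constant", "params": {"value": 82.5}},
      "gmax": {"soma_dend": 82.5, "AIS": 0.0, "axon": 0.0},
      "coupling": {"slope": 0.814, "intercept": 3.36},
      "kinetics_link": {"tau_ratio": 50.0, "v50_shift": 50.0},
      "gmax_range": [15.0, 150.0],
      "tau_h_range": [15.0, 150.0]
    },
    "H": {
      "m_gate": {"v50": -90.0, "slope_k": -7.25, "exponent": 1},
      "h_gate": {"v50": 0.0, "slope_k": 1.0, "exponent": 0},
      "e_rev": -40.0,
      "tau_m": {"rule_id": "h_m", "params": {}},
      "tau_h": {"rule_id": "constant", "params": {"value": 1.0}},
      "gmax": {"soma_dend": 1.375, "AIS": 0.0, "axon": 0.0},
      "gmax_range": [0.25, 2.5],
      "v50_range": [-100.0, -80.0]
    },
    "CaL": {
      "m_gate": {"v50": -31.0, "slope_k": 7.0, "exponent": 1},
      "h_gate": {"v50": 0.0, "slope_k": 1.0, "exponent": 0},
      "e_rev": 120.0,
      "tau_m": {"rule_id": "cal_m", "params": {}},
      "tau_h": {"rule_id": "constant", "params": {"value": 1.0}},
      "gmax": {"soma_dend": 1.0, "AIS": 0.0, "axon": 0.0}
    },
    "SK": {
      "_comment": "Calcium-gated, no voltage gates; open fraction ca^4/(ca^4+K^4), K in mM; treated as instantaneous.",
      "e_rev": -90.0,
      "hill_k": 0.00019,
      "hill_n": 4,
      "gmax": {"soma_dend": 0.125, "AIS": 0.0, "axon": 0.0}
    },
    "leak": {
      "_comment": "Conductance is 1/specific_membrane_resistance = 0.1 pS/um^2 for Rm = 100 kOhm cm^2.",
      "e_rev": -50.0,
      "gmax": {"soma_dend": 0.1, "AIS": 0.1, "axon": 0.1}
    }
  },
  "passive": {
    "axial_resistivity_ohm_cm": 150.0,
    "specific_capacitance_uF_cm2": 0.75,
    "specific_membrane_resistance_ohm_cm2": 100000.0,
    "e_leak_mV": -50.0
  },
  "calcium": {
    "shell_depth_um": 1.0,
    "decay_tau_ms": 5.0,
    "baseline_mM": 5e-05
  }
}
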