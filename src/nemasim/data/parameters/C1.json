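{
  "level": "C1",
  "baseline_chem": 0.01,
  "baseline_gap": 0.01,
  "neuron": {
    "model": "conductance",
    "C_m": 3.0,
    "g_leak": 0.3,
    "E_leak": -60.0,
    "ca_rho": 0.002,
    "ca_tau": 150.0,
    "spike_detect_threshold": -20.0,
    "channels": [
      {
        "name": "k_slow",
        "gbar": 0.3,
        "E_rev": -80.0,
        "activation": {
          "V_half": -45.0,
          "slope_k": 5.0,
          "tau": 60.0,
          "exponent": 1
        },
        "inactivation": null,
        "is_calcium_carrier": false
      },
      {
        "name": "ca",
        "gbar": 0.6,
        "E_rev": 60.0,
        "activation": {
          "V_half": -35.0,
          "slope_k": 4.0,
          "tau": 5.0,
          "exponent": 2
        },
        "inactivation": {
          "V_half": -48.0,
          "slope_k": -4.0,
          "tau": 150.0,
          "exponent": 1
        },
        "is_calcium_carrier": true
      }
    ]
  },
  "muscle": {
    "model": "conductance",
    "C_m": 20.0,
    "g_leak": 0.2,
    "E_leak": -60.0,
    "ca_rho": 0.0002,
    "ca_tau": 200.0,
    "spike_detect_threshold": -20.0,
    "channels": [
      {
        "name": "k_fast",
        "gbar": 3.0,
        "E_rev": -80.0,
        "activation": {
          "V_half": -25.0,
          "slope_k": 10.0,
          "tau": 2.0,
          "exponent": 4
        },
        "inactivation": {
          "V_half": -50.0,
          "slope_k": -8.0,
          "tau": 150.0,
          "exponent": 1
        },
        "is_calcium_carrier": false
      },
      {
        "name": "k_slow",
        "gbar": 1.0,
        "E_rev": -80.0,
        "activation": {
          "V_half": -35.0,
          "slope_k": 8.0,
          "tau": 80.0,
          "exponent": 1
        },
        "inactivation": null,
        "is_calcium_carrier": false
      },
      {
        "name": "ca",
        "gbar": 4.0,
        "E_rev": 60.0,
        "activation": {
          "V_half": -44.0,
          "slope_k": 3.0,
          "tau": 3.0,
          "exponent": 2
        },
        "inactivation": {
          "V_half": -54.0,
          "slope_k": -4.0,
          "tau": 120.0,
          "exponent": 1
        },
        "is_calcium_carrier": true
      }
    ]
  },
  "exc_syn": {
    "model": "graded",
    "g_base": 1.0,
    "E_syn": 0.0,
    "V_th_pre": -40.0,
    "delta": 3.0,
    "tau_s": 80.0
  },
  "inh_syn": {
    "model": "graded",
    "g_base": 1.0,
    "E_syn": -70.0,
    "V_th_pre": -40.0,
    "delta": 3.0,
    "tau_s": 80.0
  },
  "gap": {
    "g_gap": 1.0
  },
  "activity": null
}
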