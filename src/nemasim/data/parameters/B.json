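{
  "level": "B",
  "baseline_chem": 0.01,
  "baseline_gap": 0.01,
  "neuron": {
    "model": "lif",
    "C_m": 3.0,
    "g_leak": 0.1,
    "E_leak": -60.0,
    "V_thresh": -40.0,
    "V_reset": -65.0,
    "t_refract": 2.0
  },
  "muscle": {
    "model": "lif",
    "C_m": 20.0,
    "g_leak": 0.4,
    "E_leak": -60.0,
    "V_thresh": -40.0,
    "V_reset": -65.0,
    "t_refract": 2.0
  },
  "exc_syn": {
    "model": "spike",
    "g_base": 1.0,
    "E_syn": 0.0,
    "tau_decay": 20.0
  },
  "inh_syn": {
    "model": "spike",
    "g_base": 1.0,
    "E_syn": -70.0,
    "tau_decay": 20.0
  },
  "gap": {
    "g_gap": 1.0
  },
  "activity": {
    "tau_activity": 250.0,
    "increment_per_spike": 1.0
  }
}
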