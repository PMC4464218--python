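{
  "input_device": {"alpha": 4.0, "delta": 0.05, "k": 700.0, "eta": 0.9, "logic": "activating"},
  "tetr_ptet": {"alpha": 3.0, "delta": 0.05, "k": 0.2, "eta": 2.0, "logic": "repressing"},
  "laci_plac": {"alpha": 0.5, "delta": 1e-05, "k": 3.2, "eta": 1.9, "logic": "repressing"},
  "yes_gate": {"alpha": 3.0, "delta": 0.05, "k": 0.2, "eta": 2.0, "logic": "activating"}
}
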