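name: fig3_scan
study: sensitivity
gate: tetr_ptet
noise_model: constant_cv
entities: [0.15, 0.55, 0.75]
n_cells: 10000
seed: 1
output: fig3_scan.csv
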