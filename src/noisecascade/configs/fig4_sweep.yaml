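name: fig4_sweep
study: extrinsic
gate: tetr_ptet
noise_model: constant_cv
entities: [0.15, 0.55, 0.75]
output2_noise: {model: constant_cv, level: 0.15}
rho_grid: [0.0, 0.25, 0.5, 0.75, 1.0]
n_cells: 10000
seed: 1
output: fig4_sweep.csv
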