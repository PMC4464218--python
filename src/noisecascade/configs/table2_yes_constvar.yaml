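name: table2_yes_constvar
study: characterize
gate: yes_gate
noise_model: constant_var
entities: [0.05, 0.1, 0.15]
n_cells: 10000
seed: 1
output: table2_yes_constvar.csv
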