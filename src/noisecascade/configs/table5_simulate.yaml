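name: table5_simulate
study: blackbox_simulate
entities: [0.15, 0.55, 0.75]
entities2: [0.15, 0.55, 0.75]
rho: 0.0
n_cells: 10000
seed: 1
output: table5.csv
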