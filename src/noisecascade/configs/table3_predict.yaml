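name: table3_predict
study: blackbox_predict
noise_model: constant_cv
entities: [0.15, 0.55, 0.75]
n_cells: 10000
seed: 1
output: table3_constcv.csv
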