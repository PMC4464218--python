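name: table4_reference
study: blackbox_reference
seed: 1
output: table4.csv
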