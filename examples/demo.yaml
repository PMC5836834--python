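seed: 42
n_genes: 1000
frac_oscillating: 0.5
noise_sd: 0.5
n_terms: 30
genes_per_term: 25
planted:
  - [0, 0.8]
  - [3, 0.8]
filter_permutations: 999
phase_boot: 199
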