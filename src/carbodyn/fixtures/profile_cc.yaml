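barrier_kcal_mol: 7.43
barrier_center: 0.45
barrier_sigma: 0.15
tilt: 0.8
wall_k: 40.0
wall_edge: 1.1
range:
- 0.0
- 2.5
bins: 100
temperature_K: 330.0
n_samples: 20000000
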