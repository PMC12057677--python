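radius_A: 2.83
sigma_A: 0.1
n_oxygens: 8
n_frames: 2000
box_A: 12.44
dr_A: 0.02
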