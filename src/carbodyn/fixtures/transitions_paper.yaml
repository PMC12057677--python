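p_indirect: 0.8902
n_motifs: 5000
run_frames: 3
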