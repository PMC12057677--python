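source_weights:
  CT: 0.581
  CC: 0.419
hop_distribution:
  2: 0.65
  3: 0.15
  4: 0.09
  5: 0.05
  6: 0.03
  7: 0.015
  8: 0.01
  9: 0.005
endpoint_probs:
  CT:
    homing: 0.8295
  CC:
    homing: 0.5776
rattle_rate: 0.3
n_waters: 12
box_A: 12.44
dt_ps: 0.1
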