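states:
- H2CO3_CC
- H2CO3_CT
- H2CO3_TT
- HCO3
- CO3
stationary:
- 0.813
- 0.124
- 0.003
- 0.05995
- 5.0e-05
flows:
- - H2CO3_CC
  - H2CO3_CT
  - 0.02
- - H2CO3_CT
  - H2CO3_TT
  - 0.004
- - H2CO3_CC
  - HCO3
  - 0.01
- - H2CO3_CT
  - HCO3
  - 0.01
- - HCO3
  - CO3
  - 0.0002
dt_ps: 0.1
co3_bound_pct: 0.01
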