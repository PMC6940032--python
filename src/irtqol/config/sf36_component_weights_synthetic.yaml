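# SYNTHETIC component-summary weights for SF-36 (PCS / MCS).
#
# The classical physical and mental component summaries z-score the 8
# subscales against general-population norms, apply factor-score
# coefficients, and linearly transform to mean 50 / SD 10.  The norm means,
# SDs, and coefficients are published under license and are NOT reproduced
# here: the numbers below are a synthetic, structurally faithful stand-in
# (physically oriented subscales weight positively on PCS and slightly
# negatively on MCS, and vice versa).  Replace this file with licensed
# coefficients for norm-based scoring.
reference_means:
  PF: 70.0
  RP: 65.0
  BP: 70.0
  GH: 60.0
  VT: 60.0
  SF: 75.0
  RE: 70.0
  MH: 70.0
reference_sds:
  PF: 25.0
  RP: 35.0
  BP: 25.0
  GH: 21.0
  VT: 21.0
  SF: 24.0
  RE: 33.0
  MH: 18.0
weights:
  physical:
    PF: 0.42
    RP: 0.35
    BP: 0.32
    GH: 0.25
    VT: 0.03
    SF: -0.01
    RE: -0.19
    MH: -0.22
  mental:
    PF: -0.23
    RP: -0.12
    BP: -0.10
    GH: -0.02
    VT: 0.24
    SF: 0.27
    RE: 0.43
    MH: 0.49
transform:
  center: 50.0
  scale: 10.0
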