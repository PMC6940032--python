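# SF-36 subscale scoring tables (RAND-style linear recoding).
#
# Provenance: the classical scoring recodes each item to the 0-100 scale
# and averages the member items of each of the 8 subscales.  The tables
# below assume responses are already keyed so that a HIGHER category code
# means BETTER health (reverse-keying is a schema/upstream concern), and
# recode the K categories linearly onto 0-100 — the even-spacing variant
# popularized by the RAND scoring rules.  Published proprietary scorings
# differ for a few precoded items (e.g., bodily pain); edit the per-item
# value lists to reproduce them.  The health-transition item sf2 is
# conventionally reported separately; here it is grouped with general
# health (consistent with the latent-structure clustering).
#
# Missing policy: a subscale is computed from the mean of its present
# items when at least half of its member items are present (half-scale
# rule), otherwise it is missing.
subscales:
  PF: [sf3, sf4, sf5, sf6, sf7, sf8, sf9, sf10, sf11, sf12]
  RP: [sf13, sf14, sf15, sf16]
  BP: [sf21, sf22]
  GH: [sf1, sf2, sf33, sf34, sf35, sf36]
  VT: [sf23, sf27, sf29, sf31]
  SF: [sf20, sf32]
  RE: [sf17, sf18, sf19]
  MH: [sf24, sf25, sf26, sf28, sf30]
items:
  sf1: {values: [0, 25, 50, 75, 100]}
  sf2: {values: [0, 25, 50, 75, 100]}
  sf3: {values: [0, 50, 100]}
  sf4: {values: [0, 50, 100]}
  sf5: {values: [0, 50, 100]}
  sf6: {values: [0, 50, 100]}
  sf7: {values: [0, 50, 100]}
  sf8: {values: [0, 50, 100]}
  sf9: {values: [0, 50, 100]}
  sf10: {values: [0, 50, 100]}
  sf11: {values: [0, 50, 100]}
  sf12: {values: [0, 50, 100]}
  sf13: {values: [0, 100]}
  sf14: {values: [0, 100]}
  sf15: {values: [0, 100]}
  sf16: {values: [0, 100]}
  sf17: {values: [0, 100]}
  sf18: {values: [0, 100]}
  sf19: {values: [0, 100]}
  sf20: {values: [0, 25, 50, 75, 100]}
  sf21: {values: [0, 20, 40, 60, 80, 100]}
  sf22: {values: [0, 25, 50, 75, 100]}
  sf23: {values: [0, 20, 40, 60, 80, 100]}
  sf24: {values: [0, 20, 40, 60, 80, 100]}
  sf25: {values: [0, 20, 40, 60, 80, 100]}
  sf26: {values: [0, 20, 40, 60, 80, 100]}
  sf27: {values: [0, 20, 40, 60, 80, 100]}
  sf28: {values: [0, 20, 40, 60, 80, 100]}
  sf29: {values: [0, 20, 40, 60, 80, 100]}
  sf30: {values: [0, 20, 40, 60, 80, 100]}
  sf31: {values: [0, 20, 40, 60, 80, 100]}
  sf32: {values: [0, 25, 50, 75, 100]}
  sf33: {values: [0, 25, 50, 75, 100]}
  sf34: {values: [0, 25, 50, 75, 100]}
  sf35: {values: [0, 25, 50, 75, 100]}
  sf36: {values: [0, 25, 50, 75, 100]}
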