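# United Kingdom time trade-off (TTO) value set for the 3-level EQ-5D,
# from the MVH study (Dolan 1997).  A health state is scored as the
# full-health value minus the any-dysfunction constant (applied once if any
# dimension is at level 2 or 3), minus per-dimension level decrements,
# minus the worst-level (N3) constant (applied once if any dimension is at
# level 3).  State 11111 scores 1.0; state 33333 scores -0.594.
name: uk_tto_mvh
full_health: 1.0
any_dysfunction_constant: 0.081
worst_level_constant: 0.269
dimensions: [mobility, self_care, usual_activities, pain_discomfort, anxiety_depression]
decrements:
  mobility: {2: 0.069, 3: 0.314}
  self_care: {2: 0.104, 3: 0.214}
  usual_activities: {2: 0.036, 3: 0.094}
  pain_discomfort: {2: 0.123, 3: 0.386}
  anxiety_depression: {2: 0.071, 3: 0.236}
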