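mode: synth
out_dir: out/synth
synth:
  n_subjects: 2
  trials_per_class: 60
  classes: [LEFT_HAND, RIGHT_HAND]
  channel_set: [C3, CZ, C4]
  effect_size: 0.8
  sessions_per_subject: 2
  rng_seed: 0
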