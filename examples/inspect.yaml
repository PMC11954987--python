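mode: inspect
out_dir: out/inspect
checkpoint_in: out/train/checkpoint.npz
synth:
  n_subjects: 1
  trials_per_class: 4
  effect_size: 0.8
  rng_seed: 0
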