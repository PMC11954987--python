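mode: ablate-augment
out_dir: out/ablate
synth:
  n_subjects: 2
  trials_per_class: 50
  effect_size: 0.8
  rng_seed: 3
model:
  n_blocks: 1
  n_classes: 2
policy:
  total_epochs: 30
  warmup_epochs: 5
  batch_size: 8
seeds: [1, 2, 3]
eval_holdout: 0.3
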