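mode: train-scratch
out_dir: out/train
synth:
  n_subjects: 2
  trials_per_class: 60
  effect_size: 0.8
  rng_seed: 0
model:
  n_blocks: 2
  n_classes: 2
policy:
  total_epochs: 40
  warmup_epochs: 5
  batch_size: 32
augment:
  crop_window: 512
  ops: [shift]
eval_holdout: 0.3
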