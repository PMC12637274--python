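# Desk-scale profile: the canonical small configuration used by the test
# suite and examples. Two encoder stages on 64x64 inputs keep a full
# training run in CPU minutes while exercising every architectural piece.
model:
  input_size: [64, 64, 3]
  num_classes: 4
  strides: [4, 2]
  embed_dims: [8, 16]
  depths: [1, 1]
  num_heads: [1, 2]
  expansions: [4, 4]
  decoder_dim: 32
  seed: 0
train:
  epochs: 30
  steps_per_epoch: 160
  validation_steps: 20
  batch_size: 1
  learning_rate: 1.0e-4
  clipnorm: 1.0
  plateau_factor: 0.5
  plateau_patience: 15
  min_lr: 1.0e-15
  early_stop_patience: 35
  restore_best: true
  seed: 0
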