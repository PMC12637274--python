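# Full-scale profile: 256x256 inputs, four stages, and the complete training
# protocol (600 epochs of 1000 steps with 200 validation steps at batch size
# 1). Provided for completeness; not exercised by the test suite.
model:
  input_size: [256, 256, 3]
  num_classes: 4
  strides: [4, 2, 2, 2]
  embed_dims: [32, 64, 160, 256]
  depths: [2, 2, 2, 2]
  num_heads: [1, 2, 5, 8]
  expansions: [4, 4, 4, 4]
  decoder_dim: 256
  seed: 0
train:
  epochs: 600
  steps_per_epoch: 1000
  validation_steps: 200
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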