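learning_rate: 0.01
adam_beta1: 0.8
adam_beta2: 0.999
weight_decay: 0.0005
temperature: 4.0
batch_size: 64
epochs: 300
train_frac: 0.7
image_size: 224
seed: 0
variant: full
checkpoint_every: 0
eval_every: 0
mixup:
  enabled: true
  alpha: 0.2
  factor: 4
  within_class: false
cnn:
  block_counts:
  - 3
  - 4
  - 6
  - 3
  base_width: 64
  small_stem: false
  tap_stage: auto
mvt:
  patch_size: 16
  view_dims:
  - 256
  - 384
  - 512
  layers_per_view: 4
  global_dim: 512
  global_depth: 4
  heads: 8
  tap_layer: 3
loss:
  w_epkt: 1.0
  w_fusion_ce: 1.0
  literal_total: false
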