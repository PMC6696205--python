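# Experiment presets: desk_scale runs on one CPU in about a minute;
# full_scale carries the reference training recipe.
desk_scale:
  blur_t: 3
  class_levels:
  - 0.0
  - 5.0
  - 10.0
  - 15.0
  enhance_cfg:
    base_channels: 12
    convs_per_block: 2
    global_residual: true
    growth: 6
    inception_widths:
    - 4
    - 4
    - 4
    n_rdi_blocks: 1
    scale_factor: 2
    t: 3
  enhance_train:
    batch_size: 8
    beta1: 0.9
    beta2: 0.999
    crop_size: 24
    epochs: 0
    learning_rate: 0.003
    lr_decay_every: 0
    lr_decay_factor: 0.5
    steps: 300
    weight_decay: 0.0
  eval_crops: 5
  eval_tile: 64
  extractor_width_scale: 0.0625
  level_is_variance: false
  loss_weights:
    mu: 0.01
    perceptual_layer: 8
  n_patches: 900
  n_sources: 16
  noise_cfg:
    bottleneck_channels: 12
    branch_widths:
    - 6
    - 6
    - 6
    input_size: 32
    n_classes: 4
    n_inception_blocks: 3
    pre_channels: 12
    reduction_channels: 8
  noise_train:
    batch_size: 32
    beta1: 0.9
    beta2: 0.999
    crop_size: 40
    epochs: 3
    learning_rate: 0.001
    lr_decay_every: 0
    lr_decay_factor: 0.5
    steps: 0
    weight_decay: 0.0001
  pair_split:
  - 0.75
  - 0.25
  patch_size: 32
  patch_split:
  - 0.8888888888888888
  - 0.1111111111111111
  seed: 0
  source_dir: null
  source_size: 128
  sr_sigmas:
  - 5.0
  - 10.0
  - 15.0
full_scale:
  blur_t: 15
  class_levels:
  - 0.0
  - 2.0
  - 4.0
  - 6.0
  - 8.0
  - 10.0
  - 12.0
  - 14.0
  - 16.0
  - 18.0
  enhance_cfg:
    base_channels: 128
    convs_per_block: 4
    global_residual: true
    growth: 32
    inception_widths:
    - 32
    - 32
    - 32
    n_rdi_blocks: 3
    scale_factor: 2
    t: 15
  enhance_train:
    batch_size: 20
    beta1: 0.9
    beta2: 0.999
    crop_size: 40
    epochs: 0
    learning_rate: 0.01
    lr_decay_every: 50000
    lr_decay_factor: 0.5
    steps: 200000
    weight_decay: 0.0
  eval_crops: 5
  eval_tile: 40
  extractor_width_scale: 1.0
  level_is_variance: false
  loss_weights:
    mu: 0.01
    perceptual_layer: 8
  n_patches: 42000
  n_sources: 1600
  noise_cfg:
    bottleneck_channels: 96
    branch_widths:
    - 32
    - 32
    - 32
    input_size: 100
    n_classes: 10
    n_inception_blocks: 3
    pre_channels: 96
    reduction_channels: 32
  noise_train:
    batch_size: 40
    beta1: 0.9
    beta2: 0.999
    crop_size: 40
    epochs: 40
    learning_rate: 0.001
    lr_decay_every: 0
    lr_decay_factor: 0.5
    steps: 0
    weight_decay: 0.0001
  pair_split:
  - 0.875
  - 0.125
  patch_size: 100
  patch_split:
  - 0.9523809523809523
  - 0.047619047619047616
  seed: 0
  source_dir: null
  source_size: 512
  sr_sigmas:
  - 5.0
  - 10.0
  - 15.0
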