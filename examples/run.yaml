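# Desk-scale run configuration for the mammoseg CLI workbench.
# Usage: mammoseg simulate --config examples/run.yaml --seed 1 --out runs/demo
#        (then preprocess / pretrain / finetune / evaluate / report)

phantom:
  n_images: 64
  size_mix: [0.625, 0.25, 0.125]   # 40 small / 16 medium / 8 large
  image_side: 512
  reference_side: 224              # lesion areas defined on the model grid

preprocess:
  clahe_clip_limit: 2.0
  clahe_tile_grid: 8
  target_side: 224
  mask_threshold: 0.5

sampler:
  patch_side: 224
  neg_per_pos: 2
  neg_max_coverage: 0.05
  hybrid_substitution_prob: 0.35

model:
  input_side: 224
  encoder_filters: [8, 16, 32]     # desk-scale; full scale is [64, 128, 256]
  bottleneck_filters: 64           # full scale: 512
  dropout_rate: 0.3

loss:
  focal_gamma: 2.0
  focal_alpha: 0.25
  tversky_alpha: 0.3
  tversky_beta: 0.7

stage1:
  learning_rate: 3.0e-3            # desk-scale; full scale uses 1.0e-4
  batch_size: 8
  max_epochs: 30

stage2:
  learning_rate: 1.0e-3
  batch_size: 8
  max_epochs: 30

augment: minor                     # none | minor (geometric) | full

eval:
  detection_threshold: 0.10
  size_bounds: [500, 1500]
  area_basis: model
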