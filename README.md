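# mammoseg

A tested, reusable implementation of a **two-stage hybrid U-Net pipeline for
abnormal-focused mammographic lesion segmentation**, together with the
size-stratified evaluation framework needed to characterize its
size-dependent failure modes — exercisable end-to-end on synthetic phantom
data, with no external dataset download.

## The problem

Screening mammograms are huge (4000–6000 px per side) while the lesions
that matter are tiny: a 250-pixel lesion downsampled to a 224×224 network
input retains well under one equivalent pixel. Training segmentation
networks on such data faces two compounding problems: extreme
foreground/background class imbalance, and a resolution bottleneck that
disproportionately erases small, early-stage lesions. This package
implements a training protocol designed for that regime and an evaluation
framework that makes the resulting size-dependence measurable:

* **Stage 1 — patch pretraining.** A U-Net (encoder 64/128/256 filters with
  batch norm, ReLU, 2×2 max-pooling and dropout 0.3; 512-filter bottleneck;
  transpose-convolution decoder with skip connections; 1-channel sigmoid
  head) is pretrained on 224×224 lesion-centered crops, with background
  patches sampled at a 2:1 negative:positive ratio subject to a <5%
  mask-coverage limit, split 80/20 by source image.
* **Stage 2 — hybrid fine-tuning.** Encoder and bottleneck weights transfer
  to a fresh network that is fine-tuned on full (downsampled) images; a
  hybrid generator independently replaces each training sample with a
  lesion patch with probability 0.35, so small-lesion features are not
  forgotten.
* **Loss.** A composite of focal loss (γ=2, α=0.25) and Tversky loss
  (α=0.3, β=0.7 — false negatives cost more than false positives), both
  config-exposed.
* **Evaluation.** Dice `2|A∩B|/(|A|+|B|)`, IoU `|A∩B|/|A∪B|`, pixel
  accuracy, and symmetric Hausdorff distance (defined only when both masks
  are non-empty); a lesion counts as *detected* when IoU > 0.10. Results
  stratify by mask pixel area — small (<500 px), medium (500–1500 px),
  large (>1500 px) — with Kruskal–Wallis tests across categories,
  Mann–Whitney comparison of missed vs. detected lesion sizes, and
  size–quality correlations.

The network, backpropagation, and Adam optimizer are implemented in NumPy
(with numba-accelerated convolution kernels), so the whole pipeline runs on
a plain CPU scientific Python stack.

Because real mammography datasets cannot ship with a library, the
`phantom` module generates breast-shaped synthetic images — half-ellipse
foreground, correlated parenchymal texture, irregular low-contrast blob
lesions of controlled pixel area — with exact ground-truth masks, so every
stage is testable and the qualitative size-dependence of the protocol is
reproducible from scratch.

## Worked example

```python
from mammoseg.pipeline import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(seed=1))   # ~10 min on one CPU
print(f"best validation Dice: {result.best_val_dice:.3f}")
print(result.report.to_frame()[["category", "n", "detected",
                                "detection_rate_pct"]].to_string(index=False))
```

prints (seed 1):

```
best validation Dice: 0.361
category   n  detected  detection_rate_pct
   small   8         2                25.0
  medium   3         3               100.0
   large   1         1               100.0
 overall  12         6                50.0
```

A 64-phantom cohort (40 small / 16 medium / 8 large lesions on the 224
grid) is generated, split 60/20/20 with category stratification, trained
through both stages with a reduced U-Net (8/16/32 encoder filters,
64-filter bottleneck), and evaluated on the held-out test split. The
detection rate climbs monotonically with lesion size and segmentation
quality among detected lesions is markedly higher for large lesions —
small, faint lesions are the dominant failure mode, exactly the behavior
the size-stratified framework is built to expose.

Shorter, single-capability scripts live in `examples/` (phantom
generation, preprocessing + patch sampling, losses/metrics on hand
examples, toy two-stage training, stratified evaluation arithmetic).

## Command-line workbench

Each stage is also a shell command operating on a run directory:

```bash
mammoseg simulate   --config run.yaml --seed 1 --out runs/demo
mammoseg preprocess --out runs/demo
mammoseg pretrain   --out runs/demo
mammoseg finetune   --out runs/demo
mammoseg evaluate   --out runs/demo
mammoseg report     --out runs/demo     # tables, curves, overlays
```

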