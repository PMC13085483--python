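"""End-to-end desk-scale pipeline: phantoms → two-stage training → report.

This wires the library modules into the full experiment protocol at a
scale a single CPU handles in minutes: a synthetic cohort (default 64
images of 512 px with one lesion each, 40 small / 16 medium / 8 large on
the 224 grid), a 60/20/20 train/validation/test split, Stage-1 patch
pretraining, Stage-2 full-image fine-tuning with 35% hybrid patch
substitution, and size-stratified evaluation of the held-out test set.

The reduced network (8/16/32 encoder filters, 64-filter bottleneck) keeps
the full-scale topology; desk-scale learning rates are larger than the
full-scale 1e-4 default because the model and dataset are orders of
magnitude smaller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from mammoseg.evaluate import StratifiedReport, evaluate_test_set, stratify
from mammoseg.losses import LossConfig
from mammoseg.nn import UNet, UNetConfig, build_unet
from mammoseg.patches import SamplerConfig, build_patch_dataset
from mammoseg.phantom import generate_cohort
from mammoseg.preprocess import (
    AugmentConfig,
    PreprocessConfig,
    preprocess_pair,
    resize_pair,
)
from mammoseg.train import (
    TrainConfig,
    TrainHistory,
    finetune_full_images,
    pretrain_on_patches,
    split_dataset,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    n_images: int = 64
    size_mix: tuple[float, float, float] = (40 / 64, 16 / 64, 8 / 64)
    image_side: int = 512
    reference_side: int = 224          # lesion areas defined on the model grid
    model_side: int = 224
    encoder_filters: tuple[int, ...] = (8, 16, 32)
    bottleneck_filters: int = 64
    split: tuple[float, float, float] = (0.6, 0.2, 0.2)
    stage1_epochs: int = 30
    stage2_epochs: int = 30
    stage1_lr: float = 3e-3            # desk-scale rates; full scale uses 1e-4
    stage2_lr: float = 1e-3
    batch_size: int = 8
    seed: int = 0


@dataclass
class PipelineResult:
    stage1_history: TrainHistory
    stage2_history: TrainHistory
    model: UNet
    records: list = field(default_factory=list)
    report: StratifiedReport | None = None
    manifest: object = None

    @property
    def best_val_dice(self) -> float:
        return self.stage2_history.best_val_dice


def run_pipeline(config: PipelineConfig = PipelineConfig()) -> PipelineResult:
    """Run the full two-stage protocol on a fresh synthetic cohort."""
    seed = config.seed
    log.info("generating cohort of %d phantoms", config.n_images)
    pairs, manifest = generate_cohort(
        config.n_images, config.size_mix, seed=seed,
        image_side=config.image_side, reference_side=config.reference_side)
    pp_cfg = PreprocessConfig(target_side=config.model_side)
    native = [preprocess_pair(p, pp_cfg, resize=False) for p in pairs]
    resized = [resize_pair(p, config.model_side, pp_cfg) for p in native]

    by_id = {p.id: p for p in resized}
    # category-stratified split so every size category is represented in
    # each of train/validation/test (as in the published test cohort)
    cat_of = dict(zip(manifest["id"], manifest["category"]))
    train_n, val_n, test_n = [], [], []
    for k, cat in enumerate(("small", "medium", "large")):
        group = [p for p in native if cat_of[p.id] == cat]
        if not group:
            continue
        tr, va, te = split_dataset(group, config.split, seed=seed + 1 + k)
        train_n += tr
        val_n += va
        test_n += te
    train_r = [by_id[p.id] for p in train_n]
    val_r = [by_id[p.id] for p in val_n]
    test_r = [by_id[p.id] for p in test_n]

    sampler = SamplerConfig(patch_side=config.model_side, seed=seed + 2)
    patch_train, patch_val = build_patch_dataset(train_n, sampler)
    log.info("stage 1: %d train / %d val patches", len(patch_train), len(patch_val))
    ucfg = UNetConfig(input_side=config.model_side,
                      encoder_filters=config.encoder_filters,
                      bottleneck_filters=config.bottleneck_filters,
                      init_seed=seed + 3)
    loss = LossConfig()
    model1 = build_unet(ucfg)
    model1, hist1 = pretrain_on_patches(
        model1, patch_train, patch_val, loss,
        TrainConfig(learning_rate=config.stage1_lr, batch_size=config.batch_size,
                    max_epochs=config.stage1_epochs, seed=seed + 4))

    log.info("stage 2: fine-tuning on %d full images", len(train_r))
    patch_pool = [p for p in patch_train if p.label == "positive"]
    # minor geometric augmentation only: elastic warps and contrast jitter
    # erase few-pixel lesions after mask re-binarization at this scale
    minor_aug = AugmentConfig(elastic=False, clahe_jitter=False,
                              lesion_preserving_crop=False)
    model2, hist2 = finetune_full_images(
        model1, train_r, val_r, patch_pool, loss,
        TrainConfig(learning_rate=config.stage2_lr, batch_size=config.batch_size,
                    max_epochs=config.stage2_epochs, seed=seed + 5),
        sampler, augment_config=minor_aug)

    records = evaluate_test_set(model2, test_r, area_basis="model")
    report = stratify(records)
    result = PipelineResult(stage1_history=hist1, stage2_history=hist2,
                            model=model2, records=records, report=report)
    result.manifest = manifest
    return result
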