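"""Two-stage training: patch pretraining, encoder transfer, hybrid fine-tuning.

Both stages optimize the composite focal + Tversky loss with Adam
(learning rate 1e-4 by default) and monitor the validation Dice score
(predictions binarized at 0.5) for early stopping, learning-rate decay and
best-checkpoint selection. Stage 2 starts from the Stage-1 encoder (and
bottleneck) weights via :func:`~mammoseg.nn.transfer_encoder` and draws its
training batches from the hybrid full-image/patch generator; validation
always uses full images only.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np
import pandas as pd

from mammoseg.losses import LossConfig, composite_loss_and_grad
from mammoseg.metrics import dice as dice_metric
from mammoseg.nn import Adam, UNet, build_unet, transfer_encoder
from mammoseg.patches import PatchSample, SamplerConfig, hybrid_batches
from mammoseg.phantom import ImagePair
from mammoseg.preprocess import AugmentConfig, augment

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "split_dataset",
    "pretrain_on_patches",
    "finetune_full_images",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 8
    max_epochs: int = 30
    early_stop_patience: int = 10
    lr_decay_factor: float = 0.5
    lr_decay_patience: int = 5
    min_delta: float = 1e-4
    monitor: str = "val_dice"
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if not 0 < self.lr_decay_factor <= 1:
            raise ValueError("lr_decay_factor must be in (0, 1]")


@dataclass
class TrainHistory:
    epochs: list[dict] = field(default_factory=list)
    checkpoint_epoch: int = -1
    stop_reason: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.epochs)

    @property
    def best_val_dice(self) -> float:
        if self.checkpoint_epoch < 0:
            return float("nan")
        return self.epochs[self.checkpoint_epoch]["val_dice"]


def split_dataset(items: Sequence, spec, seed: int = 0):
    """Random disjoint exhaustive partition into (train, validation, test).

    ``spec`` is either explicit counts summing to ``len(items)`` or
    fractions summing to 1 (converted to counts by largest remainder).
    """
    from mammoseg.phantom import apportion

    items = list(items)
    spec = tuple(spec)
    if len(spec) != 3:
        raise ValueError("spec must have three entries (train, val, test)")
    if all(float(s).is_integer() for s in spec) and sum(spec) > 3.0:
        counts = [int(s) for s in spec]
        if sum(counts) != len(items):
            raise ValueError(f"counts {counts} do not sum to {len(items)} items")
    else:
        if abs(sum(spec) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        counts = apportion(len(items), list(spec))
    order = np.random.default_rng(seed).permutation(len(items))
    a, b = counts[0], counts[0] + counts[1]
    return ([items[i] for i in order[:a]],
            [items[i] for i in order[a:b]],
            [items[i] for i in order[b:]])


def _validation_dice(model: UNet, val_x: np.ndarray, val_y: np.ndarray,
                     batch: int) -> float:
    """Mean per-image Dice at threshold 0.5, inference mode."""
    scores = []
    for i in range(0, len(val_x), batch):
        prob = model.forward(val_x[i:i + batch], train=False)
        pred = (prob > 0.5).astype(np.uint8)
        for j in range(len(pred)):
            scores.append(dice_metric(pred[j, 0], val_y[i + j, 0].astype(np.uint8)))
    return float(np.mean(scores))


def _stack(samples, flip_rng: np.random.Generator | None = None):
    imgs, msks = [], []
    for s in samples:
        img, msk = s[0], s[1]
        if flip_rng is not None:  # stochastic horizontal/vertical flips
            if flip_rng.random() < 0.5:
                img, msk = img[:, ::-1], msk[:, ::-1]
            if flip_rng.random() < 0.5:
                img, msk = img[::-1, :], msk[::-1, :]
        imgs.append(img)
        msks.append(msk)
    return (np.stack(imgs)[:, None].astype(np.float32),
            np.stack(msks)[:, None].astype(np.float32))


def _train_loop(model: UNet,
                batch_provider: Callable[[int, np.random.Generator],
                                         Iterator[tuple[np.ndarray, np.ndarray]]],
                val_x: np.ndarray, val_y: np.ndarray,
                loss: LossConfig, config: TrainConfig,
                stage: str) -> tuple[UNet, TrainHistory]:
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params(), lr=config.learning_rate)
    history = TrainHistory()
    best = -np.inf
    best_state = None
    since_improve = 0
    since_decay = 0
    for epoch in range(config.max_epochs):
        losses = []
        for x, y in batch_provider(epoch, rng):
            opt.zero_grad()
            prob = model.forward(x, train=True, rng=rng)
            lval, dprob = composite_loss_and_grad(prob, y, loss)
            model.backward(dprob.astype(np.float32))
            opt.step()
            losses.append(lval)
        val_dice = _validation_dice(model, val_x, val_y, config.batch_size)
        history.epochs.append({
            "epoch": epoch,
            "train_loss": float(np.mean(losses)) if losses else float("nan"),
            "val_dice": val_dice,
            "lr": opt.lr,
        })
        log.info("[%s] epoch %d loss=%.4f val_dice=%.4f lr=%.2e",
                 stage, epoch, history.epochs[-1]["train_loss"], val_dice, opt.lr)
        if val_dice > best + config.min_delta:
            best = val_dice
            best_state = model.state_dict()
            history.checkpoint_epoch = epoch
            since_improve = 0
            since_decay = 0
        else:
            since_improve += 1
            since_decay += 1
            if since_decay >= config.lr_decay_patience:
                opt.lr *= config.lr_decay_factor
                since_decay = 0
                log.info("[%s] lr decayed to %.2e", stage, opt.lr)
            if since_improve >= config.early_stop_patience:
                history.stop_reason = f"early stop after {since_improve} stale epochs"
                break
    if not history.stop_reason:
        history.stop_reason = "max_epochs reached"
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history


def pretrain_on_patches(model: UNet,
                        patch_train: Sequence[PatchSample],
                        patch_val: Sequence[PatchSample],
                        loss: LossConfig, config: TrainConfig
                        ) -> tuple[UNet, TrainHistory]:
    """Stage 1: fit the network to lesion-centered patches.

    Horizontal/vertical flips are applied stochastically to training
    patches each epoch. The returned model carries the best-validation-Dice
    weights.
    """
    if not patch_train:
        raise ValueError("empty patch training split")
    if not patch_val:
        raise ValueError("empty patch validation split")
    val_x, val_y = _stack([(p.image_crop, p.mask_crop) for p in patch_val])
    items = [(p.image_crop, p.mask_crop) for p in patch_train]

    def provider(epoch: int, rng: np.random.Generator):
        order = rng.permutation(len(items))
        for i in range(0, len(order), config.batch_size):
            chunk = [items[j] for j in order[i:i + config.batch_size]]
            yield _stack(chunk, flip_rng=rng)

    return _train_loop(model, provider, val_x, val_y, loss, config, "stage1")


def finetune_full_images(pretrained: UNet,
                         full_train: Sequence[ImagePair],
                         full_val: Sequence[ImagePair],
                         patch_pool: Sequence[PatchSample],
                         loss: LossConfig, config: TrainConfig,
                         sampler: SamplerConfig = SamplerConfig(),
                         augment_config: AugmentConfig | None = None,
                         ) -> tuple[UNet, TrainHistory]:
    """Stage 2: fine-tune on full images with hybrid patch substitution.

    A fresh network with the same architecture receives the pretrained
    encoder + bottleneck weights; the decoder restarts from its
    initialization. When ``augment_config`` is given, full-image training
    samples are re-augmented each epoch; validation uses untouched full
    images only. For few-pixel lesions prefer geometry-preserving
    augmentation (flips/rotation/zoom) — elastic warps and contrast jitter
    can destroy the lesion signal outright at small scales.
    """
    if not full_train:
        raise ValueError("empty full-image training split")
    if not full_val:
        raise ValueError("empty full-image validation split")
    model = build_unet(pretrained.config)
    model, _copied = transfer_encoder(pretrained, model)
    val_x, val_y = _stack([(p.image, p.mask) for p in full_val])

    def provider(epoch: int, rng: np.random.Generator):
        train = full_train
        if augment_config is not None:
            train = [augment(p, augment_config, rng) for p in full_train]
        for x, y, _prov in hybrid_batches(train, patch_pool, sampler, rng,
                                          batch_size=config.batch_size):
            yield x, y

    return _train_loop(model, provider, val_x, val_y, loss, config, "stage2")
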