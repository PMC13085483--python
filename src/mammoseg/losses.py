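"""Composite focal + Tversky training loss for sparse lesion masks.

Focal loss re-weights per-pixel cross-entropy by ``(1 - p_t)^gamma`` so that
easily classified background pixels contribute little, and by ``alpha_t`` to
balance the positive/negative classes. Tversky loss generalizes soft-Dice
with separate false-positive (``alpha``) and false-negative (``beta``)
penalties; ``beta > alpha`` makes missed lesion pixels more expensive, the
sensitivity-oriented setting appropriate when lesions are a tiny fraction of
the image. The training objective is a weighted sum of the two.

Each loss has a value function (the public API) and a fused value-and-
gradient used by the trainer; gradients are with respect to the predicted
probability map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LossConfig",
    "focal_loss",
    "tversky_loss",
    "composite_loss",
    "composite_loss_and_grad",
]


@dataclass(frozen=True)
class LossConfig:
    """Parameters of the composite loss.

    Defaults: focal ``gamma=2, alpha=0.25`` (the standard focal-loss
    settings) and Tversky ``alpha=0.3, beta=0.7`` to penalize false
    negatives more heavily; both components enter with unit weight.
    """

    focal_gamma: float = 2.0
    focal_alpha: float = 0.25
    tversky_alpha: float = 0.3
    tversky_beta: float = 0.7
    mix_focal: float = 1.0
    mix_tversky: float = 1.0
    smooth_eps: float = 1e-6

    def __post_init__(self):
        if self.focal_gamma < 0:
            raise ValueError("focal_gamma must be >= 0")
        if not 0.0 < self.focal_alpha < 1.0:
            raise ValueError("focal_alpha must be in (0, 1)")
        if self.tversky_alpha + self.tversky_beta <= 0:
            raise ValueError("tversky_alpha + tversky_beta must be > 0")
        if self.mix_focal < 0 or self.mix_tversky < 0 or \
                (self.mix_focal == 0 and self.mix_tversky == 0):
            raise ValueError("mix weights must be >= 0 and not both 0")
        if self.smooth_eps <= 0:
            raise ValueError("smooth_eps must be > 0")


def _check(prob: np.ndarray, gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    prob = np.asarray(prob, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    if prob.shape != gt.shape:
        raise ValueError(f"shape mismatch: prob {prob.shape} vs gt {gt.shape}")
    return prob, gt


def focal_loss(prob: np.ndarray, gt: np.ndarray, config: LossConfig = LossConfig()) -> float:
    """Mean over pixels of ``-alpha_t (1 - p_t)^gamma log(p_t)``."""
    prob, gt = _check(prob, gt)
    eps = config.smooth_eps
    p = np.clip(prob, eps, 1.0 - eps)
    pt = np.where(gt > 0.5, p, 1.0 - p)
    at = np.where(gt > 0.5, config.focal_alpha, 1.0 - config.focal_alpha)
    return float(np.mean(-at * (1.0 - pt) ** config.focal_gamma * np.log(pt)))


def _focal_grad(prob: np.ndarray, gt: np.ndarray, config: LossConfig) -> np.ndarray:
    eps = config.smooth_eps
    g = config.focal_gamma
    p = np.clip(prob, eps, 1.0 - eps)
    pos = gt > 0.5
    pt = np.where(pos, p, 1.0 - p)
    at = np.where(pos, config.focal_alpha, 1.0 - config.focal_alpha)
    one_m = 1.0 - pt
    # d/dpt of -(1-pt)^g log(pt)
    dpt = g * one_m ** (g - 1.0) * np.log(pt) - one_m ** g / pt if g > 0 \
        else -1.0 / pt
    dl_dpt = at * dpt
    dl_dp = np.where(pos, dl_dpt, -dl_dpt)
    return dl_dp / prob.size


def _tversky_terms(prob, gt, axis):
    tp = (prob * gt).sum(axis=axis)
    fp = (prob * (1.0 - gt)).sum(axis=axis)
    fn = ((1.0 - prob) * gt).sum(axis=axis)
    return tp, fp, fn


def tversky_loss(prob: np.ndarray, gt: np.ndarray, config: LossConfig = LossConfig()) -> float:
    """``1 - (TP + eps) / (TP + alpha*FP + beta*FN + eps)`` with soft counts.

    With ``alpha = beta = 0.5`` this reduces to the soft-Dice loss.
    """
    prob, gt = _check(prob, gt)
    tp, fp, fn = _tversky_terms(prob, gt, axis=None)
    eps = config.smooth_eps
    denom = tp + config.tversky_alpha * fp + config.tversky_beta * fn
    return float(1.0 - (tp + eps) / (denom + eps))


def _tversky_grad(prob: np.ndarray, gt: np.ndarray, config: LossConfig) -> np.ndarray:
    eps = config.smooth_eps
    a, b = config.tversky_alpha, config.tversky_beta
    tp, fp, fn = _tversky_terms(prob, gt, axis=None)
    denom = tp + a * fp + b * fn + eps
    num = tp + eps
    # dTP/dp = g, dFP/dp = 1-g, dFN/dp = -g
    ddenom = gt + a * (1.0 - gt) - b * gt
    dT = (gt * denom - num * ddenom) / denom ** 2
    return -dT


def composite_loss(prob: np.ndarray, gt: np.ndarray,
                   config: LossConfig = LossConfig()) -> float:
    """``mix_focal * focal + mix_tversky * tversky``."""
    total = 0.0
    if config.mix_focal:
        total += config.mix_focal * focal_loss(prob, gt, config)
    if config.mix_tversky:
        total += config.mix_tversky * tversky_loss(prob, gt, config)
    return float(total)


def composite_loss_and_grad(prob: np.ndarray, gt: np.ndarray,
                            config: LossConfig = LossConfig()
                            ) -> tuple[float, np.ndarray]:
    """Loss and its gradient w.r.t. ``prob``, averaged per sample for batches.

    For a 4-D ``(N, 1, H, W)`` batch the Tversky term is computed per sample
    and averaged (each image contributes one overlap ratio); the focal term
    is a mean over all pixels either way.
    """
    prob, gt = _check(prob, gt)
    grad = np.zeros_like(prob)
    total = 0.0
    if config.mix_focal:
        total += config.mix_focal * focal_loss(prob, gt, config)
        grad += config.mix_focal * _focal_grad(prob, gt, config)
    if config.mix_tversky:
        if prob.ndim == 4:
            n = prob.shape[0]
            vals = []
            for i in range(n):
                vals.append(tversky_loss(prob[i], gt[i], config))
                grad[i] += config.mix_tversky * _tversky_grad(prob[i], gt[i], config) / n
            total += config.mix_tversky * float(np.mean(vals))
        else:
            total += config.mix_tversky * tversky_loss(prob, gt, config)
            grad += config.mix_tversky * _tversky_grad(prob, gt, config)
    return float(total), grad
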