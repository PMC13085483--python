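"""The composite focal+Tversky loss and the evaluation metrics on a hand pair.

Two 4-pixel strip masks overlapping in 2 pixels give closed-form values:
Dice 0.5, IoU 1/3, Tversky loss 0.5 (alpha=0.3, beta=0.7).
"""

import numpy as np

from mammoseg import (
    LossConfig,
    composite_loss,
    dice,
    focal_loss,
    hausdorff_symmetric,
    iou,
    pixel_accuracy,
    tversky_loss,
)

gt = np.zeros((8, 8)); gt[0, :4] = 1
pred = np.zeros((8, 8)); pred[0, 2:6] = 1

print("Binary overlap metrics (|gt|=4, |pred|=4, overlap 2):")
print(f"  Dice            = {dice(pred.astype(np.uint8), gt.astype(np.uint8)):.4f}")
print(f"  IoU             = {iou(pred.astype(np.uint8), gt.astype(np.uint8)):.4f}")
print(f"  pixel accuracy  = {pixel_accuracy(pred.astype(np.uint8), gt.astype(np.uint8)):.4f}")
print(f"  Hausdorff       = {hausdorff_symmetric(pred.astype(np.uint8), gt.astype(np.uint8)):.1f} px")

cfg = LossConfig(focal_gamma=2.0, focal_alpha=0.25,
                 tversky_alpha=0.3, tversky_beta=0.7, smooth_eps=1e-12)
print("\nTraining losses on the hard prediction treated as probabilities:")
print(f"  focal (gamma=2, alpha=0.25)     = {focal_loss(pred, gt, cfg):.4f}")
print(f"  Tversky (alpha=0.3, beta=0.7)   = {tversky_loss(pred, gt, cfg):.4f}")
print(f"  composite (sum of the two)      = {composite_loss(pred, gt, cfg):.4f}")
print("\nbeta > alpha makes false negatives (missed lesion pixels) costlier "
      "than false positives - the sensitivity-oriented setting for sparse lesions.")
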