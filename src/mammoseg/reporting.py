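"""Results-style tables, training curves, and prediction overlays.

Table 1 style: overall metric summary (mean/median/SD, Hausdorff over
defined cases only). Table 2 style: per-size-category detection counts and
rates. Table 3 style: per-category metric means ± SD among detected
lesions with the Kruskal–Wallis statistics.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from mammoseg.evaluate import EvalRecord, StratifiedReport, records_to_frame

__all__ = [
    "overall_summary_table",
    "detection_table",
    "stratified_metric_table",
    "write_report",
    "plot_history",
    "save_overlay",
]


def overall_summary_table(records: Sequence[EvalRecord]) -> pd.DataFrame:
    """Mean/median/SD of Dice, IoU, pixel accuracy and (defined) Hausdorff."""
    rows = []
    for name in ("dice", "iou", "pixel_accuracy"):
        vals = np.array([getattr(r, name) for r in records], dtype=float)
        rows.append({"metric": name, "mean": vals.mean(), "median": float(np.median(vals)),
                     "sd": vals.std(ddof=1) if len(vals) > 1 else 0.0, "n": len(vals)})
    hd = [r.hausdorff for r in records if r.hausdorff is not None]
    rows.append({"metric": "hausdorff_px",
                 "mean": float(np.mean(hd)) if hd else None,
                 "median": float(np.median(hd)) if hd else None,
                 "sd": float(np.std(hd, ddof=1)) if len(hd) > 1 else (0.0 if hd else None),
                 "n": len(hd)})
    return pd.DataFrame(rows)


def detection_table(report: StratifiedReport) -> pd.DataFrame:
    """Per-category ground-truth/detected/missed counts and detection rate."""
    return report.to_frame()[["category", "n", "detected", "missed",
                              "detection_rate_pct", "mean_area"]]


def stratified_metric_table(report: StratifiedReport) -> pd.DataFrame:
    df = report.to_frame()[["category", "dice_mean_detected", "dice_sd_detected",
                            "iou_mean_detected", "iou_sd_detected"]]
    meta = pd.DataFrame([
        {"category": "kruskal_dice",
         "dice_mean_detected": report.kruskal_dice[0] if report.kruskal_dice else None,
         "dice_sd_detected": report.kruskal_dice[1] if report.kruskal_dice else None,
         "iou_mean_detected": report.kruskal_iou[0] if report.kruskal_iou else None,
         "iou_sd_detected": report.kruskal_iou[1] if report.kruskal_iou else None},
    ])
    return pd.concat([df, meta], ignore_index=True)


def report_to_json(report: StratifiedReport, records: Sequence[EvalRecord]) -> dict:
    def cat(c):
        return {
            "n": c.n, "detected": c.n_detected, "missed": c.n_missed,
            "detection_rate_pct": c.detection_rate_pct,
            "mean_area": c.mean_area,
            "dice_mean_detected": c.dice_mean, "dice_sd_detected": c.dice_sd,
            "iou_mean_detected": c.iou_mean, "iou_sd_detected": c.iou_sd,
        }

    return {
        "categories": {k: cat(v) for k, v in report.categories.items()},
        "overall": cat(report.overall),
        "missed_share_pct": report.missed_share_pct,
        "kruskal_dice": report.kruskal_dice,
        "kruskal_iou": report.kruskal_iou,
        "missed_vs_detected": report.missed_vs_detected,
        "corr_dice": report.corr_dice,
        "corr_iou": report.corr_iou,
        "overall_mean_dice_including_missed": report.overall_mean_dice_including_missed,
        "overall_mean_iou_including_missed": report.overall_mean_iou_including_missed,
        "n_records": len(records),
    }


def write_report(outdir, report: StratifiedReport,
                 records: Sequence[EvalRecord]) -> None:
    """Emit records.csv, the three Results-style tables, and report.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records_to_frame(records).to_csv(outdir / "records.csv", index=False)
    overall_summary_table(records).to_csv(outdir / "table1_overall.csv", index=False)
    detection_table(report).to_csv(outdir / "table2_detection.csv", index=False)
    stratified_metric_table(report).to_csv(outdir / "table3_stratified.csv", index=False)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report_to_json(report, records), fh, indent=2)


def plot_history(histories: dict[str, pd.DataFrame], path) -> None:
    """Loss and validation-Dice curves per training stage (one PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for name, df in histories.items():
        axes[0].plot(df["epoch"], df["train_loss"], label=name)
        axes[1].plot(df["epoch"], df["val_dice"], label=name)
    axes[0].set_xlabel("epoch"); axes[0].set_ylabel("training loss")
    axes[1].set_xlabel("epoch"); axes[1].set_ylabel("validation Dice")
    for ax in axes:
        ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_overlay(image: np.ndarray, gt_mask: np.ndarray, pred_mask: np.ndarray,
                 path, title: str = "") -> None:
    """Prediction (red) vs ground-truth (green) boundaries over the image."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from skimage.segmentation import find_boundaries

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(image, cmap="gray", vmin=0, vmax=1)
    gt_b = find_boundaries(gt_mask.astype(bool), mode="outer")
    pr_b = find_boundaries(pred_mask.astype(bool), mode="outer")
    overlay = np.zeros((*image.shape, 4))
    overlay[gt_b] = (0, 1, 0, 1)
    overlay[pr_b] = (1, 0, 0, 1)
    ax.imshow(overlay)
    ax.set_axis_off()
    if title:
        ax.set_title(title, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
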