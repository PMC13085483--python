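"""Size-stratified detection analysis and the resolution budget.

Feeds the stratifier a record set with known per-category detected/missed
counts (37 small / 13 medium / 5 large with 27/11/5 detected) and prints
the detection-rate table, the group tests, and the resolution arithmetic
that explains why small lesions get lost.
"""

from mammoseg.evaluate import (
    EvalRecord,
    detect,
    resolution_analysis,
    size_category,
    stratify,
)

records = []
i = 0
for n, n_det, area in ((37, 27, 220.0), (13, 11, 840.0), (5, 5, 5100.0)):
    for k in range(n):
        iou = 0.5 if k < n_det else 0.02      # detected iff IoU > 0.10
        records.append(EvalRecord(
            id=f"r{i}", dice=2 * iou / (1 + iou), iou=iou, pixel_accuracy=0.99,
            hausdorff=None, lesion_area=area + k, area_basis="native",
            detected=detect(iou), size_category=size_category(area + k)))
        i += 1

report = stratify(records)
print(report.to_frame()[["category", "n", "detected", "missed",
                         "detection_rate_pct"]].to_string(index=False))
print(f"\nMissed share: {report.missed_share_pct:.1f}%")
mv = report.missed_vs_detected
print(f"Missed lesions average {mv['mean_area_missed']:.1f} px vs "
      f"{mv['mean_area_detected']:.1f} px for detected "
      f"(Mann-Whitney p = {mv['mannwhitney_p']:.2e})")

print("\nResolution budget for a 250-px lesion downsampled to 224:")
for native in (4000, 6000):
    fold, equiv = resolution_analysis(native, 224, 250)
    print(f"  native {native} px: {fold:.1f}-fold linear reduction -> "
          f"{equiv:.2f} equivalent pixels")
print("Below ~1 equivalent pixel a per-pixel classifier has nothing left "
      "to segment - the architectural bottleneck behind small-lesion misses.")
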