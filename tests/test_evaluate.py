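"""Evaluation: detection rule, stratification, statistics, resolution math."""

import numpy as np
import pytest
from scipy import stats as sps

from mammoseg.evaluate import (
    EvalRecord,
    compare_missed_vs_detected,
    detect,
    evaluate_test_set,
    kruskal_wallis,
    mann_whitney_u,
    resolution_analysis,
    size_category,
    size_quality_correlation,
    stratify,
)


def record(area, iou_val=0.5, dice_val=None, detected=None, rid="r"):
    dice_val = 2 * iou_val / (1 + iou_val) if dice_val is None else dice_val
    det = detect(iou_val) if detected is None else detected
    return EvalRecord(id=rid, dice=dice_val, iou=iou_val, pixel_accuracy=0.99,
                      hausdorff=None, lesion_area=area, area_basis="native",
                      detected=det, size_category=size_category(area))


class TestDetect:
    def test_strict_inequality_at_threshold(self):
        assert not detect(0.10)
        assert detect(0.10 + 1e-12)

    @pytest.mark.parametrize("iou,expected", [(0.0, False), (0.11, True), (1.0, True)])
    def test_values(self, iou, expected):
        assert detect(iou) is expected

    def test_monotone_in_threshold(self, rng):
        ious = rng.random(50)
        rates = [np.mean([detect(v, t) for v in ious]) for t in (0.05, 0.1, 0.3, 0.6)]
        assert all(a >= b for a, b in zip(rates, rates[1:]))


class TestSizeCategory:
    def test_boundary_assignment(self):
        assert [size_category(a) for a in (499, 500, 1500, 1501)] == \
            ["small", "medium", "medium", "large"]


class TestStratify:
    def _published_counts_records(self):
        """Synthetic records mirroring the 37/13/5 categories with
        27/11/5 detected."""
        recs = []
        i = 0
        for (n, det, area) in ((37, 27, 220.0), (13, 11, 840.0), (5, 5, 5100.0)):
            for k in range(n):
                is_det = k < det
                recs.append(record(area + k, iou_val=0.5 if is_det else 0.02,
                                   rid=f"r{i}"))
                i += 1
        return recs

    def test_detection_rates_match_hand_arithmetic(self):
        report = stratify(self._published_counts_records())
        assert report.categories["small"].detection_rate_pct == pytest.approx(100 * 27 / 37)
        assert report.categories["medium"].detection_rate_pct == pytest.approx(100 * 11 / 13)
        assert report.categories["large"].detection_rate_pct == pytest.approx(100.0)
        assert report.overall.detection_rate_pct == pytest.approx(100 * 43 / 55)
        assert report.missed_share_pct == pytest.approx(100 * 12 / 55)

    def test_partition_and_count_consistency(self):
        report = stratify(self._published_counts_records())
        total = 0
        for c in report.categories.values():
            assert c.n_detected + c.n_missed == c.n
            total += c.n
        assert total == report.overall.n == 55

    def test_single_category_others_undefined(self):
        recs = [record(100.0, iou_val=0.9, rid=f"r{i}") for i in range(4)]
        report = stratify(recs)
        assert report.categories["small"].detection_rate_pct == 100.0
        assert report.categories["large"].n == 0
        assert report.categories["large"].detection_rate_pct is None

    def test_overall_mean_includes_missed_scores(self):
        recs = [record(100, iou_val=0.8, rid="a"), record(100, iou_val=0.0, rid="b")]
        report = stratify(recs)
        expected = np.mean([r.dice for r in recs])
        assert report.overall_mean_dice_including_missed == pytest.approx(expected)
        # mean among detected only is higher
        assert report.categories["small"].dice_mean > expected

    def test_overall_rate_path_independent(self, rng):
        recs = [record(float(rng.uniform(50, 3000)), iou_val=float(rng.random()),
                       rid=f"r{i}") for i in range(40)]
        report = stratify(recs)
        assert report.overall.detection_rate_pct == pytest.approx(
            100 * sum(r.detected for r in recs) / len(recs))


class TestKruskalWallis:
    def test_hand_example_h72(self):
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2, abs=1e-9)
        assert p == pytest.approx(float(sps.chi2.sf(7.2, 2)), abs=1e-12)

    def test_identical_groups_h_zero(self):
        h, _ = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(0.0, abs=1e-9)

    def test_all_identical_values_degenerate(self):
        h, p = kruskal_wallis([[5, 5], [5, 5, 5]])
        assert (h, p) == (0.0, 1.0)

    def test_matches_scipy_on_100_random_instances(self, rng):
        for _ in range(100):
            groups = [rng.integers(0, 12, size=int(rng.integers(3, 10))).astype(float)
                      for _ in range(int(rng.integers(2, 5)))]
            if all((g == groups[0][0]).all() for g in groups):
                continue
            h, p = kruskal_wallis(groups)
            h_ref, p_ref = sps.kruskal(*groups)
            assert h == pytest.approx(h_ref, abs=1e-9)
            assert p == pytest.approx(p_ref, abs=1e-9)


class TestMannWhitney:
    def test_matches_scipy_asymptotic_on_100_instances(self, rng):
        for _ in range(100):
            x = rng.integers(0, 25, size=int(rng.integers(3, 15))).astype(float)
            y = rng.integers(0, 25, size=int(rng.integers(3, 15))).astype(float)
            u, p = mann_whitney_u(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
            assert u == pytest.approx(ref.statistic, abs=1e-9)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_separated_groups_significant(self):
        _, p = mann_whitney_u(list(range(1, 11)), list(range(101, 111)))
        assert p < 0.001


class TestMissedVsDetected:
    def test_hand_means(self):
        recs = [record(100, detected=False, rid="a"), record(300, detected=False, rid="b"),
                record(900, detected=True, rid="c"), record(1300, detected=True, rid="d")]
        out = compare_missed_vs_detected(recs)
        assert out["mean_area_missed"] == pytest.approx(200.0)
        assert out["mean_area_detected"] == pytest.approx(1100.0)

    def test_identical_groups_p_near_one(self):
        recs = [record(a, detected=(i % 2 == 0), rid=str(i))
                for i, a in enumerate([100, 100, 200, 200, 300, 300, 400, 400])]
        out = compare_missed_vs_detected(recs)
        assert out["mannwhitney_p"] > 0.8

    def test_one_group_empty_marks_test_undefined(self):
        recs = [record(100, detected=True, rid="a"), record(200, detected=True, rid="b")]
        out = compare_missed_vs_detected(recs)
        assert out["mean_area_missed"] is None
        assert out["mannwhitney_p"] is None


class TestCorrelation:
    def test_perfect_linearity(self):
        recs = [record(a, detected=True, dice_val=d, iou_val=0.5, rid=str(a))
                for a, d in [(1, 0.2), (2, 0.4), (3, 0.6)]]
        assert size_quality_correlation(recs, "dice") == pytest.approx(1.0)

    def test_null_simulation_near_zero(self, rng):
        recs = [record(float(rng.uniform(10, 5000)), detected=True,
                       dice_val=float(rng.random()), iou_val=0.5, rid=str(i))
                for i in range(2000)]
        r = size_quality_correlation(recs, "dice")
        assert abs(r) < 0.06

    def test_constant_metric_undefined(self):
        recs = [record(a, detected=True, dice_val=0.5, iou_val=0.5, rid=str(a))
                for a in (1, 2, 3)]
        assert size_quality_correlation(recs, "dice") is None


class TestResolutionAnalysis:
    def test_published_endpoints(self):
        fold_hi, equiv_hi = resolution_analysis(4000, 224, 250)
        fold_lo, equiv_lo = resolution_analysis(6000, 224, 250)
        assert fold_hi == pytest.approx(17.857142857, abs=1e-6)
        assert fold_lo == pytest.approx(26.785714285, abs=1e-6)
        assert round(equiv_hi, 1) == 0.8
        assert round(equiv_lo, 1) == 0.3

    def test_identity_resolution(self):
        fold, equiv = resolution_analysis(224, 224, 123)
        assert fold == 1.0
        assert equiv == pytest.approx(123.0)

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            resolution_analysis(0, 224, 100)


class TestEvaluateTestSet:
    class _Oracle:
        """Stand-in model returning the ground truth (or zeros)."""

        def __init__(self, pairs, zeros=False):
            self._masks = {id(p.image.tobytes()): None for p in pairs}
            self.pairs = {p.image.tobytes(): p.mask for p in pairs}
            self.zeros = zeros

        def forward(self, x, train=False):
            out = np.zeros_like(x, dtype=np.float32)
            if not self.zeros:
                for i in range(x.shape[0]):
                    m = self.pairs[x[i, 0].tobytes()]
                    out[i, 0] = m.astype(np.float32)
            return np.clip(out, 1e-6, 1 - 1e-6)

    def _pairs(self):
        from mammoseg.phantom import ImagePair

        rng = np.random.default_rng(0)
        out = []
        for i in range(6):
            img = rng.random((64, 64)).astype(np.float32)
            msk = np.zeros((64, 64), np.uint8)
            msk[10:20, 10:20 + i] = 1
            out.append(ImagePair(id=f"t{i}", image=img, mask=msk, native_side=64))
        return out

    def test_oracle_model_all_detected(self):
        pairs = self._pairs()
        recs = evaluate_test_set(self._Oracle(pairs), pairs, area_basis="model")
        assert all(r.dice == 1.0 and r.detected for r in recs)

    def test_zero_model_none_detected_hausdorff_undefined(self):
        pairs = self._pairs()
        recs = evaluate_test_set(self._Oracle(pairs, zeros=True), pairs,
                                 area_basis="model")
        assert all(not r.detected and r.dice == 0.0 and r.hausdorff is None
                   for r in recs)

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError):
            evaluate_test_set(None, [])
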