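"""Per-segment features and the segmentation quality measure."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from cfuseg import (
    Segment,
    circles_to_mask,
    extract_features,
    features_table,
    quality_mean,
    quality_q,
    SegmentationResult,
)


def _disc_mask(radius, size=None, center=None):
    size = size or int(2 * radius) + 10
    cy, cx = center or (size / 2, size / 2)
    yy, xx = np.mgrid[:size, :size].astype(float)
    return np.hypot(yy - cy, xx - cx) <= radius


class TestFeatures:
    def test_disc_radius_and_roundness(self):
        seg = Segment.from_mask(_disc_mask(20))
        rec = extract_features(seg)
        assert rec["equiv_radius_px"] == pytest.approx(20, rel=0.02)
        assert rec["eccentricity"] < 0.2

    def test_single_pixel_conventions(self):
        m = np.zeros((5, 5), dtype=bool)
        m[2, 2] = True
        rec = extract_features(Segment.from_mask(m))
        assert rec["area_px"] == 1
        assert rec["equiv_radius_px"] == pytest.approx(np.sqrt(1 / np.pi))
        assert rec["eccentricity"] == 0.0

    def test_elongated_rectangle_is_eccentric(self):
        m = np.zeros((50, 20), dtype=bool)
        m[5:45, 5:15] = True  # 40 x 10
        assert extract_features(Segment.from_mask(m))["eccentricity"] > 0.9

    def test_table_has_frozen_columns(self):
        lm = _disc_mask(6).astype(np.int32)
        res = SegmentationResult.from_label_mask(lm, np.full(lm.shape, 0.5))
        df = features_table(res, image_name="img1")
        assert list(df.columns) == [
            "image", "segment_id", "area_px", "equiv_radius_px", "eccentricity",
            "mean_intensity", "centroid_row", "centroid_col",
        ]
        assert df.loc[0, "mean_intensity"] == pytest.approx(0.5)


class TestQualityQ:
    def test_identical_masks_are_perfect(self):
        lm = _disc_mask(8).astype(np.int32)
        rep = quality_q(lm, lm)
        assert (rep.Q, rep.q1, rep.q2) == (1.0, 0.0, 0.0)

    def test_count_deviation_reference_value(self):
        gt = np.zeros((300, 300), dtype=np.int32)
        pred = np.zeros_like(gt)
        k = 0
        for i in range(48):
            r, c = divmod(i, 7)
            gt[4 + r * 40 : 6 + r * 40, 4 + c * 40 : 6 + c * 40] = i + 1
            if i < 40:
                pred[4 + r * 40 : 6 + r * 40, 4 + c * 40 : 6 + c * 40] = i + 1
            k += 1
        rep = quality_q(pred, gt)
        assert rep.n_truth == 48 and rep.n_detected == 40
        assert rep.q1 == pytest.approx(16.7, abs=0.05)

    def test_empty_prediction_scores_zero(self):
        gt = _disc_mask(8).astype(np.int32)
        rep = quality_q(np.zeros_like(gt), gt)
        assert rep.q2 == 1.0 and rep.Q == 0.0

    def test_empty_ground_truth_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            quality_q(_disc_mask(8).astype(np.int32), np.zeros((26, 26), dtype=np.int32))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            quality_q(np.ones((4, 4), dtype=np.int32), np.ones((5, 5), dtype=np.int32))

    def test_invariant_under_relabeling(self):
        gt = np.zeros((40, 40), dtype=np.int32)
        gt[2:10, 2:10] = 1
        gt[20:30, 20:30] = 2
        pred = gt.copy()
        pred[pred == 1] = 7
        pred[pred == 2] = 3
        assert quality_q(pred, gt) == quality_q(gt, gt)

    def test_monotone_degradation_under_corruption(self):
        rng = np.random.default_rng(11)
        gt = np.zeros((60, 60), dtype=np.int32)
        gt[10:30, 10:30] = 1
        gt[40:55, 40:55] = 2
        fg = np.flatnonzero(gt.ravel())
        order = rng.permutation(fg)
        qs = []
        for level in range(21):
            pred = gt.copy().ravel()
            pred[order[: int(level / 20 * len(order))]] = 0
            qs.append(quality_q(pred.reshape(gt.shape), gt).Q)
        assert all(a >= b - 1e-12 for a, b in zip(qs, qs[1:]))
        assert qs[0] == 1.0

    def test_q1_depends_only_on_counts_q2_only_on_pixels(self):
        gt = np.zeros((40, 40), dtype=np.int32)
        gt[2:10, 2:10] = 1
        gt[20:30, 20:30] = 2
        # same pixels, split one object into two labels: q2 unchanged, q1 moves
        pred = gt.copy()
        pred[2:10, 2:6] = 3
        ra, rb = quality_q(gt, gt), quality_q(pred, gt)
        assert rb.q2 == ra.q2 == 0.0 and rb.q1 > ra.q1
        # same counts, shifted pixels: q1 unchanged, q2 moves
        pred2 = np.roll(gt, 2, axis=1)
        rc = quality_q(pred2, gt)
        assert rc.q1 == 0.0 and rc.q2 > 0.0

    def test_union_denominator_option(self):
        gt = np.zeros((20, 20), dtype=np.int32)
        gt[5:15, 5:15] = 1
        pred = np.roll(gt, 3, axis=0)
        a = quality_q(pred, gt, q2_denominator="gt")
        b = quality_q(pred, gt, q2_denominator="union")
        assert b.q2 < a.q2  # union denominator is larger


class TestQualityMean:
    def test_single_report_is_itself(self):
        lm = _disc_mask(8).astype(np.int32)
        rep = quality_q(lm, lm)
        assert quality_mean([rep]) == (1.0, 0.0)

    def test_mean_of_perfect_and_empty(self):
        lm = _disc_mask(8).astype(np.int32)
        r1 = quality_q(lm, lm)
        r2 = quality_q(np.zeros_like(lm), lm)
        qm, q1m = quality_mean([r1, r2])
        assert qm == 0.5
        assert quality_mean([r2, r1]) == (qm, q1m)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            quality_mean([])


class TestCirclesToMask:
    def test_disjoint_circles_rasterized(self):
        lm = circles_to_mask([((30.0, 30.0), 10.0), ((80.0, 80.0), 15.0)], (120, 120))
        assert lm.max() == 2
        a1 = (lm == 1).sum()
        a2 = (lm == 2).sum()
        assert abs(a1 - np.pi * 100) / (np.pi * 100) <= 0.03
        assert abs(a2 - np.pi * 225) / (np.pi * 225) <= 0.03

    def test_overlapping_circles_separated(self):
        lm = circles_to_mask([((50.0, 40.0), 15.0), ((50.0, 55.0), 15.0)], (100, 100))
        assert lm.max() == 2
        _, n = ndi.label(lm > 0)
        assert n == 1  # touching union, two labels

    def test_empty_list_gives_empty_mask(self):
        assert circles_to_mask([], (10, 10)).sum() == 0

    def test_fully_outside_circle_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="outside"):
            lm = circles_to_mask([((-50.0, -50.0), 5.0), ((20.0, 20.0), 5.0)], (40, 40))
        assert lm.max() == 1 and (lm == 1).sum() > 0

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            circles_to_mask([((5.0, 5.0), 0.0)], (10, 10))
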