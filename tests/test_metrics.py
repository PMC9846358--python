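"""Evaluation protocol: NMS, matching, P/R/F1, AP, stratified report."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from yolop.losses import BBox, iou
from yolop.metrics import (Detection, ImageEval, average_precision, match,
                           nms, precision_recall_f1, stratified_report)


def det(cx, cy, w, h, conf, image_id=None):
    return Detection(BBox(cx, cy, w, h), conf, image_id)


class TestNMS:
    def test_single_detection_survives(self):
        d = det(5, 5, 2, 2, 0.7)
        assert nms([d], 0.5) == [d]

    def test_duplicate_keeps_higher_confidence(self):
        a, b = det(5, 5, 2, 2, 0.9), det(5, 5, 2, 2, 0.8)
        assert nms([a, b], 0.5) == [a]

    def test_chain_keeps_ends(self):
        # A~B IoU 0.6, B~C IoU 0.6, A~C IoU ~0.1; confs 0.9/0.8/0.7
        a = det(0.0, 0, 4, 4, 0.9)
        b = det(1.0, 0, 4, 4, 0.8)
        c = det(2.0, 0, 4, 4, 0.7)
        assert iou(a.box, b.box) == pytest.approx(0.6)
        assert iou(a.box, c.box) == pytest.approx(1 / 3)
        survivors = nms([a, b, c], 0.5)
        assert survivors == [a, c]

    def test_matches_greedy_brute_force(self, rng):
        for _ in range(20):
            dets = [det(rng.uniform(0, 20), rng.uniform(0, 20),
                        rng.uniform(2, 8), rng.uniform(2, 8),
                        float(rng.uniform(0.05, 1.0))) for _ in range(12)]
            thresh = 0.45
            # brute-force reference enumeration of the greedy rule
            order = sorted(range(len(dets)),
                           key=lambda i: (-dets[i].confidence, i))
            keep = []
            for i in order:
                if all(iou(dets[i].box, dets[j].box) <= thresh for j in keep):
                    keep.append(i)
            ref = [dets[i] for i in sorted(keep)]
            assert nms(dets, thresh) == ref

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            nms([], 1.5)


class TestMatch:
    def test_perfect_detections(self):
        gts = [BBox(5, 5, 4, 4), BBox(20, 20, 6, 6)]
        dets = [det(5, 5, 4, 4, 0.9), det(20, 20, 6, 6, 0.8)]
        assert match(dets, gts) == (2, 0, 0)

    def test_duplicate_detection_penalised(self):
        gts = [BBox(5, 5, 4, 4)]
        dets = [det(5, 5, 4, 4, 0.9), det(5.5, 5, 4, 4, 0.8)]
        assert match(dets, gts) == (1, 1, 0)

    def test_confidence_gate_discards_low_scores(self):
        gts = [BBox(5, 5, 4, 4), BBox(20, 20, 4, 4), BBox(40, 40, 4, 4)]
        dets = [det(5, 5, 4, 4, 0.9), det(20, 20, 4, 4, 0.5),
                det(40, 40, 4, 4, 0.3)]
        assert match(dets, gts, conf_thresh=0.4) == (2, 0, 1)

    @given(n_det=st.integers(0, 12), n_gt=st.integers(0, 8),
           seed=st.integers(0, 1000))
    @settings(max_examples=40, deadline=None)
    def test_count_conservation(self, n_det, n_gt, seed):
        r = np.random.default_rng(seed)
        dets = [det(r.uniform(0, 40), r.uniform(0, 40), r.uniform(2, 9),
                    r.uniform(2, 9), float(r.uniform())) for _ in range(n_det)]
        gts = [BBox(r.uniform(0, 40), r.uniform(0, 40), r.uniform(2, 9),
                    r.uniform(2, 9)) for _ in range(n_gt)]
        tp, fp, fn = match(dets, gts)
        kept = sum(d.confidence >= 0.4 for d in dets)
        assert tp + fp == kept
        assert tp + fn == n_gt

    @given(seed=st.integers(0, 500))
    @settings(max_examples=30, deadline=None)
    def test_recall_monotone_in_confidence_threshold(self, seed):
        r = np.random.default_rng(seed)
        dets = [det(r.uniform(0, 30), r.uniform(0, 30), r.uniform(2, 8),
                    r.uniform(2, 8), float(r.uniform())) for _ in range(10)]
        gts = [BBox(r.uniform(0, 30), r.uniform(0, 30), r.uniform(2, 8),
                    r.uniform(2, 8)) for _ in range(5)]
        recalls = []
        for thresh in (0.8, 0.6, 0.4, 0.2, 0.01):
            tp, _, fn = match(dets, gts, conf_thresh=thresh)
            recalls.append(tp / (tp + fn))
        assert all(b >= a - 1e-12 for a, b in zip(recalls, recalls[1:]))


class TestPRF1:
    def test_worked_example(self):
        p, r, f1 = precision_recall_f1(9, 1, 2)
        assert p == pytest.approx(0.9)
        assert r == pytest.approx(9 / 11, abs=1e-4)
        assert f1 == pytest.approx(2 * 0.9 * (9 / 11) / (0.9 + 9 / 11),
                                   abs=1e-4)
        assert f1 == pytest.approx(0.8571, abs=1e-4)

    def test_degenerate_counts(self):
        assert precision_recall_f1(0, 0, 0) == (0.0, 0.0, 0.0)

    def test_perfect_counts(self):
        assert precision_recall_f1(7, 0, 0) == (1.0, 1.0, 1.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            precision_recall_f1(-1, 0, 0)


def _ap_oracle(dets, gts_per_image, iou_thresh=0.5):
    """Exhaustive cutoff enumeration: match every confidence prefix from
    scratch, envelope-integrate the resulting (R, P) staircase."""
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
    n_gt = sum(len(v) for v in gts_per_image.values())
    points = []
    for k in range(1, len(order) + 1):
        taken = {key: [False] * len(v) for key, v in gts_per_image.items()}
        tp = 0
        for di in order[:k]:
            d = dets[di]
            best, best_iou = -1, iou_thresh
            for gi, g in enumerate(gts_per_image.get(d.image_id, [])):
                if taken[d.image_id][gi]:
                    continue
                v = iou(d.box, g)
                if v >= best_iou:
                    best, best_iou = gi, v
            if best >= 0:
                taken[d.image_id][best] = True
                tp += 1
        points.append((tp / n_gt, tp / k))
    ap = 0.0
    prev_r = 0.0
    for i, (r, p) in enumerate(points):
        if r > prev_r:
            best_p = max(pp for rr, pp in points[i:] if rr >= r)
            ap += (r - prev_r) * best_p
            prev_r = r
    return ap


class TestAveragePrecision:
    def test_all_hits_before_any_miss(self):
        gts = {0: [BBox(5, 5, 4, 4), BBox(20, 20, 4, 4)]}
        dets = [det(5, 5, 4, 4, 0.9, 0), det(20, 20, 4, 4, 0.8, 0),
                det(40, 40, 4, 4, 0.7, 0)]
        assert average_precision(dets, gts) == 1.0

    def test_worked_four_detection_example(self):
        # 3 gts; ranked TP, TP, FP, TP -> 1/3 + 1/3 + 1/4 = 0.9167
        gts = {0: [BBox(5, 5, 4, 4), BBox(20, 20, 4, 4), BBox(35, 35, 4, 4)]}
        dets = [det(5, 5, 4, 4, 0.9, 0), det(20, 20, 4, 4, 0.8, 0),
                det(50, 50, 4, 4, 0.7, 0), det(35, 35, 4, 4, 0.6, 0)]
        ap = average_precision(dets, gts)
        assert ap == pytest.approx(1 / 3 + 1 / 3 + 1 / 4, abs=1e-6)
        assert ap == pytest.approx(_ap_oracle(dets, gts), abs=1e-9)

    def test_no_detections_give_zero(self):
        assert average_precision([], {0: [BBox(5, 5, 4, 4)]}) == 0.0

    def test_zero_gts_rejected(self):
        with pytest.raises(ValueError):
            average_precision([], {0: []})

    @given(seed=st.integers(0, 400))
    @settings(max_examples=40, deadline=None)
    def test_matches_exhaustive_cutoff_oracle(self, seed):
        r = np.random.default_rng(seed)
        n_img = int(r.integers(1, 3))
        gts = {i: [BBox(r.uniform(5, 45), r.uniform(5, 45), r.uniform(3, 10),
                        r.uniform(3, 10)) for _ in range(r.integers(1, 4))]
               for i in range(n_img)}
        dets = [det(r.uniform(0, 50), r.uniform(0, 50), r.uniform(3, 10),
                    r.uniform(3, 10), float(r.uniform()),
                    int(r.integers(0, n_img)))
                for _ in range(r.integers(1, 10))]
        assert average_precision(dets, gts) \
            == pytest.approx(_ap_oracle(dets, gts), abs=1e-9)

    def test_invariant_to_monotone_confidence_transform(self, rng):
        gts = {0: [BBox(rng.uniform(5, 45), rng.uniform(5, 45), 6, 6)
                   for _ in range(4)]}
        dets = [det(rng.uniform(0, 50), rng.uniform(0, 50), 6, 6,
                    float(rng.uniform(0.01, 0.99)), 0) for _ in range(8)]
        base = average_precision(dets, gts)
        squeezed = [det(d.box.cx, d.box.cy, d.box.w, d.box.h,
                        d.confidence ** 3, 0) for d in dets]
        assert average_precision(squeezed, gts) == pytest.approx(base)

    def test_invariant_to_image_ordering(self, rng):
        gts = {i: [BBox(10 + 10 * i, 10, 6, 6)] for i in range(3)}
        dets = [det(10 + 10 * i, 10, 6, 6, 0.9 - 0.1 * i, i)
                for i in range(3)] + [det(45, 45, 6, 6, 0.5, 0)]
        base = average_precision(dets, gts)
        relabeled_gts = {2 - k: v for k, v in gts.items()}
        relabeled = [det(d.box.cx, d.box.cy, d.box.w, d.box.h, d.confidence,
                         2 - d.image_id) for d in dets]
        assert average_precision(relabeled, relabeled_gts) \
            == pytest.approx(base)


class TestStratifiedReport:
    def _image(self, tp=1, fp=0, fn=0, shade="not_or_slight",
               tier="moderate", illum="day"):
        """Engineer an image with exactly the requested counters."""
        gts, shades, dets = [], [], []
        x = 10.0
        for _ in range(tp):
            gts.append(BBox(x, 10, 6, 6))
            shades.append(shade)
            dets.append(det(x, 10, 6, 6, 0.9))
            x += 15
        for _ in range(fn):
            gts.append(BBox(x, 10, 6, 6))
            shades.append(shade)
            x += 15
        for _ in range(fp):
            dets.append(det(x, 40, 6, 6, 0.8))
            x += 15
        return ImageEval(dets, gts, shades, tier, illum)

    def test_single_stratum_equals_overall(self):
        images = [self._image(tp=3, fp=1, fn=2)]
        res = stratified_report(images)
        assert (res.tp, res.fp, res.fn) == (3, 1, 2)
        tier_counts = res.strata[("tier", "moderate")]
        assert (tier_counts.tp, tier_counts.fp, tier_counts.fn) == (3, 1, 2)
        assert tier_counts.prf1[2] == pytest.approx(res.f1)

    def test_identical_strata_average_equals_each(self):
        from yolop.metrics import axis_f1_table

        images = [self._image(tp=2, fp=1, fn=1, tier="uncomplicated"),
                  self._image(tp=2, fp=1, fn=1, tier="extreme")]
        res = stratified_report(images)
        table = axis_f1_table(res, "tier")
        assert table["uncomplicated"] == pytest.approx(table["extreme"])
        assert table["average"] == pytest.approx(table["uncomplicated"])

    def test_engineered_counters_reproduce_hand_f1(self):
        # stratum A (day): TP=4 FP=1 FN=1; stratum B (night): TP=2 FP=2 FN=2
        images = [self._image(tp=4, fp=1, fn=1, illum="day"),
                  self._image(tp=2, fp=2, fn=2, illum="night")]
        res = stratified_report(images)
        day = res.strata[("illumination", "day")]
        night = res.strata[("illumination", "night")]
        # hand arithmetic: P=4/5, R=4/5 -> F1=0.8; P=2/4, R=2/4 -> F1=0.5
        assert day.prf1[2] == pytest.approx(0.8)
        assert night.prf1[2] == pytest.approx(0.5)
        # pooled overall: TP=6 FP=3 FN=3 -> P=R=F1=2/3
        assert res.f1 == pytest.approx(2 / 3)

    def test_beyond_scope_objects_excluded_by_default(self):
        img = ImageEval([det(10, 10, 6, 6, 0.9)],
                        [BBox(10, 10, 6, 6), BBox(30, 30, 6, 6)],
                        ["not_or_slight", "beyond_scope"],
                        "moderate", "day")
        res = stratified_report([img])
        assert (res.tp, res.fp, res.fn) == (1, 0, 0)
        assert ("shade", "beyond_scope") not in res.strata
        res2 = stratified_report([img], include_beyond_scope=True)
        assert res2.fn == 1

    def test_missing_metadata_warns_and_goes_untagged(self):
        img = ImageEval([det(10, 10, 6, 6, 0.9)], [BBox(10, 10, 6, 6)],
                        [None], None, "day")
        with pytest.warns(UserWarning):
            res = stratified_report([img])
        assert ("tier", "untagged") in res.strata
        assert ("shade", "untagged") in res.strata
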