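"""Detection post-processing and the evaluation protocol.

Greedy NMS, confidence-gated greedy matching (confidence threshold 0.4,
IoU threshold 0.5), precision / recall / F1, all-point-interpolated AP@0.5
(single class, so AP = mAP), and pooled stratified reporting by shade
degree, background complexity and day/night.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .losses import BBox, iou

SHADE_CATEGORIES = ("not_or_slight", "medium", "serious", "beyond_scope")
COMPLEXITY_TIERS = ("uncomplicated", "moderate", "extreme")
ILLUMINATIONS = ("day", "night")
UNTAGGED = "untagged"


@dataclass
class Detection:
    box: BBox
    confidence: float
    image_id: str | int | None = None

    def __post_init__(self):
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")


@dataclass
class StratumCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def prf1(self):
        return precision_recall_f1(self.tp, self.fp, self.fn)


@dataclass
class EvalResult:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    ap50: float
    strata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------

def nms(dets: list[Detection], iou_thresh: float = 0.45) -> list[Detection]:
    """Greedy suppression by descending confidence.

    Ties break on the smaller original index; every surviving pair overlaps
    by at most ``iou_thresh``.
    """
    if not 0.0 < iou_thresh < 1.0:
        raise ValueError("iou_thresh must lie in (0, 1)")
    if not dets:
        return []
    boxes = np.array([[d.box.cx - d.box.w / 2, d.box.cy - d.box.h / 2,
                       d.box.cx + d.box.w / 2, d.box.cy + d.box.h / 2]
                      for d in dets])
    areas = (boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1])
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
    keep: list[int] = []
    alive = np.ones(len(dets), dtype=bool)
    for i in order:
        if not alive[i]:
            continue
        keep.append(i)
        iw = np.minimum(boxes[:, 2], boxes[i, 2]) - np.maximum(boxes[:, 0],
                                                               boxes[i, 0])
        ih = np.minimum(boxes[:, 3], boxes[i, 3]) - np.maximum(boxes[:, 1],
                                                               boxes[i, 1])
        inter = np.clip(iw, 0, None) * np.clip(ih, 0, None)
        ious = inter / (areas + areas[i] - inter)
        alive &= ious <= iou_thresh
    return [dets[i] for i in sorted(keep)]


def match(dets: list[Detection], gts: list[BBox], conf_thresh: float = 0.4,
          iou_thresh: float = 0.5, return_pairs: bool = False):
    """Greedy one-to-one matching of detections against ground truths.

    Detections below ``conf_thresh`` are discarded; survivors claim, in
    descending confidence order, the unmatched ground truth of highest
    IoU >= ``iou_thresh``.  Leftover detections are FP, leftover ground
    truths FN.  Counts conserve: tp + fp = kept detections, tp + fn = gts.
    """
    kept = [(i, d) for i, d in enumerate(dets) if d.confidence >= conf_thresh]
    kept.sort(key=lambda t: (-t[1].confidence, t[0]))
    taken = [False] * len(gts)
    pairs = []          # (det index, gt index)
    unmatched_dets = []
    for di, d in kept:
        best, best_iou = -1, iou_thresh
        for gi, g in enumerate(gts):
            if taken[gi]:
                continue
            v = iou(d.box, g)
            if v >= best_iou:
                best, best_iou = gi, v
        if best >= 0:
            taken[best] = True
            pairs.append((di, best))
        else:
            unmatched_dets.append(di)
    tp = len(pairs)
    fp = len(unmatched_dets)
    fn = len(gts) - tp
    if return_pairs:
        return tp, fp, fn, pairs, unmatched_dets
    return tp, fp, fn


def precision_recall_f1(tp: int, fp: int, fn: int):
    """P, R and F1 from counts, with the convention P=R=F1=0 when a
    denominator vanishes."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def average_precision(dets: list[Detection], gts_per_image: dict,
                      iou_thresh: float = 0.5,
                      interpolation: str = "all_point") -> float:
    """Area under the precision-recall curve swept over confidence.

    Detections carry image ids; each, in descending confidence order, claims
    the unmatched ground truth of its image with highest IoU >= thresh.
    ``interpolation``: "all_point" (precision envelope, the default) or
    "eleven_point".
    """
    n_gt = sum(len(v) for v in gts_per_image.values())
    if n_gt == 0:
        raise ValueError("average precision needs at least one ground truth")
    order = sorted(range(len(dets)),
                   key=lambda i: (-dets[i].confidence, i))
    taken = {k: [False] * len(v) for k, v in gts_per_image.items()}
    tps = np.zeros(len(order))
    for rank, di in enumerate(order):
        d = dets[di]
        gts = gts_per_image.get(d.image_id, [])
        best, best_iou = -1, iou_thresh
        for gi, g in enumerate(gts):
            if taken[d.image_id][gi]:
                continue
            v = iou(d.box, g)
            if v >= best_iou:
                best, best_iou = gi, v
        if best >= 0:
            taken[d.image_id][best] = True
            tps[rank] = 1.0
    if len(order) == 0:
        return 0.0
    tp_cum = np.cumsum(tps)
    fp_cum = np.cumsum(1.0 - tps)
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    if interpolation == "eleven_point":
        ap = 0.0
        for r in np.linspace(0, 1, 11):
            mask = recall >= r
            ap += (precision[mask].max() if mask.any() else 0.0) / 11.0
        return float(ap)
    # all-point: integrate the precision envelope over recall
    mrec = np.concatenate(([0.0], recall, [1.0]))
    mpre = np.concatenate(([0.0], precision, [0.0]))
    for i in range(len(mpre) - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    idx = np.where(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


# ---------------------------------------------------------------------------
# stratified evaluation
# ---------------------------------------------------------------------------

@dataclass
class ImageEval:
    """Per-image inputs to the stratified report."""

    detections: list          # Detection list (post NMS)
    gt_boxes: list            # BBox list
    gt_shade: list            # shade category per gt (or None)
    tier: str | None = None
    illumination: str | None = None


def stratified_report(images: list[ImageEval], conf_thresh: float = 0.4,
                      iou_thresh: float = 0.5,
                      include_beyond_scope: bool = False) -> EvalResult:
    """Pooled counters and F1 per stratum plus per-axis averages.

    Counters pool over images (not per-image averaging).  Image-level axes
    (complexity tier, illumination) receive every TP/FP/FN of their images.
    The shade axis is object-level: TP and FN go to the category of the
    ground truth; an FP detection is attributed to the shade category of the
    ground truth it overlaps most in its image ("untagged" when the image
    has none).  Objects with shade >= 0.6 (beyond_scope) are excluded from
    matching and reporting unless ``include_beyond_scope``.  Missing
    metadata lands in an "untagged" stratum with a warning.
    """
    import warnings

    strata: dict[tuple[str, str], StratumCounts] = {}

    def bump(axis, key, kind, n=1):
        if key is None:
            key = UNTAGGED
        c = strata.setdefault((axis, key), StratumCounts())
        setattr(c, kind, getattr(c, kind) + n)

    total = StratumCounts()
    all_dets, gts_per_image = [], {}
    untagged_seen = False
    for img_id, im in enumerate(images):
        keep_idx = [i for i, cat in enumerate(im.gt_shade)
                    if include_beyond_scope or cat != "beyond_scope"]
        gts = [im.gt_boxes[i] for i in keep_idx]
        cats = [im.gt_shade[i] for i in keep_idx]
        if any(c is None for c in cats) or im.tier is None \
                or im.illumination is None:
            untagged_seen = True
        tp, fp, fn, pairs, unmatched = match(im.detections, gts, conf_thresh,
                                             iou_thresh, return_pairs=True)
        total.tp += tp
        total.fp += fp
        total.fn += fn
        for axis, key in (("tier", im.tier), ("illumination", im.illumination)):
            bump(axis, key, "tp", tp)
            bump(axis, key, "fp", fp)
            bump(axis, key, "fn", fn)
        matched_gts = {gi for _, gi in pairs}
        for _, gi in pairs:
            bump("shade", cats[gi], "tp")
        for gi in range(len(gts)):
            if gi not in matched_gts:
                bump("shade", cats[gi], "fn")
        for di in unmatched:
            best, best_v = None, 0.0
            for gi, g in enumerate(gts):
                v = iou(im.detections[di].box, g)
                if v > best_v:
                    best, best_v = cats[gi], v
            bump("shade", best, "fp")
        for d in im.detections:
            all_dets.append(Detection(d.box, d.confidence, img_id))
        gts_per_image[img_id] = gts
    if untagged_seen:
        warnings.warn("objects or images lacking metadata were placed in an "
                      "'untagged' stratum", stacklevel=2)
    p, r, f1 = total.prf1
    ap = (average_precision(all_dets, gts_per_image)
          if sum(len(v) for v in gts_per_image.values()) else 0.0)
    report = {key: counts for key, counts in sorted(strata.items())}
    return EvalResult(total.tp, total.fp, total.fn, p, r, f1, ap, report)


def axis_f1_table(result: EvalResult, axis: str) -> dict:
    """F1 per stratum of one axis plus the per-axis average."""
    rows = {key: c.prf1[2] for (a, key), c in result.strata.items() if a == axis}
    if rows:
        rows["average"] = sum(rows.values()) / len(rows)
    return rows


def render_report(result: EvalResult) -> str:
    lines = [f"overall: TP={result.tp} FP={result.fp} FN={result.fn} "
             f"P={result.precision:.3f} R={result.recall:.3f} "
             f"F1={result.f1:.3f} AP@0.5={result.ap50:.3f}"]
    for axis in ("tier", "shade", "illumination"):
        table = axis_f1_table(result, axis)
        if table:
            lines.append(f"[{axis}]")
            for key, f1 in table.items():
                lines.append(f"  {key:>16s}  F1={f1:.3f}")
    return "\n".join(lines)
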