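"""Training objective of the detector.

The loss has exactly two terms — there is no class term anywhere in the
pipeline, because the detector is single-class:

* **confidence loss** — binary cross-entropy between the sigmoid of the raw
  objectness score and an IoU-valued soft label (matched predictions carry
  their overlap with the ground truth as target; everything else is a
  negative with target 0), averaged over all anchor predictions of a scale;
* **location loss** — CIoU loss (overlap + normalised centre distance +
  aspect-ratio penalty) averaged over matched predictions.

Per-scale confidence losses are combined with fixed weights K = (6.0, 1.0,
0.5) for the small / medium / large prediction layers: distant fruit appear
small on the image and get the strongest weight.  Total = weighted
confidence + location.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .assembly import DEFAULT_ANCHORS, OUTPUTS_PER_ANCHOR, STRIDES
from .nn import Tensor
from .nn import autograd as A

_EPS = 1e-9


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass
class BBox:
    """Axis-aligned box in centre form (pixels); w, h > 0."""

    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self):
        if self.w <= 0 or self.h <= 0:
            raise ValueError("box sides must be positive")

    def corners(self):
        return (self.cx - self.w / 2, self.cy - self.h / 2,
                self.cx + self.w / 2, self.cy + self.h / 2)

    @classmethod
    def from_corners(cls, x1, y1, x2, y2):
        return cls((x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1)

    def area(self):
        return self.w * self.h


def iou(a: BBox, b: BBox) -> float:
    """Intersection over union; 0 for disjoint boxes, 1 iff identical."""
    ax1, ay1, ax2, ay2 = a.corners()
    bx1, by1, bx2, by2 = b.corners()
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = a.area() + b.area() - inter
    return inter / union


def ciou_loss(pred: BBox, gt: BBox) -> float:
    """1 - (IoU - (d^2/c^2 + alpha*v)).

    d: centre distance; c: diagonal of the smallest enclosing box; v: squared
    arctan aspect difference scaled by 4/pi^2; alpha = v / ((1 - IoU) + v),
    taken as 0 in the degenerate IoU=1, v=0 case.
    """
    if pred.w <= 0 or pred.h <= 0 or gt.w <= 0 or gt.h <= 0:
        raise ValueError("degenerate box")
    i = iou(pred, gt)
    d2 = (pred.cx - gt.cx) ** 2 + (pred.cy - gt.cy) ** 2
    px1, py1, px2, py2 = pred.corners()
    gx1, gy1, gx2, gy2 = gt.corners()
    cw = max(px2, gx2) - min(px1, gx1)
    ch = max(py2, gy2) - min(py1, gy1)
    c2 = cw * cw + ch * ch
    v = (4.0 / math.pi ** 2) * (math.atan(gt.w / gt.h)
                                - math.atan(pred.w / pred.h)) ** 2
    denom = (1.0 - i) + v
    alpha = 0.0 if denom == 0 else v / denom
    return 1.0 - (i - (d2 / c2 + alpha * v))


# ---------------------------------------------------------------------------
# confidence loss
# ---------------------------------------------------------------------------

@dataclass
class LossWeights:
    """Per-scale confidence weights; 'small' is the 80x80 (stride-8) head."""

    k_small: float = 6.0
    k_medium: float = 1.0
    k_large: float = 0.5


@dataclass
class LossBreakdown:
    conf_small: float
    conf_medium: float
    conf_large: float
    conf_weighted: float
    loc: float
    total: float


def confidence_loss(pred_conf, targets, n: int | None = None) -> float:
    """Mean binary cross-entropy of sigmoid(scores) against soft IoU labels.

    ``pred_conf`` holds raw (pre-sigmoid) scores; ``targets`` in [0, 1].
    ``n`` defaults to the number of predictions.
    """
    x = np.asarray(pred_conf, dtype=np.float64).ravel()
    t = np.asarray(targets, dtype=np.float64).ravel()
    if n is None:
        n = x.size
    if n == 0 or x.size == 0:
        raise ValueError("confidence loss needs at least one sample")
    per = np.maximum(x, 0.0) - x * t + np.log1p(np.exp(-np.abs(x)))
    return float(per.sum() / n)


def weighted_confidence_loss(per_scale, weights: LossWeights | None = None) -> float:
    w = weights or LossWeights()
    s, m, l = per_scale
    return w.k_small * s + w.k_medium * m + w.k_large * l


# ---------------------------------------------------------------------------
# target assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Assignment:
    scale: int      # 0 small / 1 medium / 2 large
    anchor: int
    gy: int
    gx: int
    gt_index: int


def assign_targets(gt_boxes, anchors=DEFAULT_ANCHORS, strides=STRIDES,
                   img_size: int = 640, ratio_thresh: float = 4.0):
    """Shape-matched anchor assignment with neighbour-cell expansion.

    A ground truth is assigned, at every scale, to each anchor whose
    width/height ratios satisfy max(r, 1/r) < ``ratio_thresh``, at its grid
    cell plus the two nearest neighbour cells (the closer horizontal and
    vertical neighbours of the box centre).  Everything else is a negative.
    ``gt_boxes``: (M, 4) array of pixel cx, cy, w, h; may be empty.
    """
    gt_boxes = np.asarray(gt_boxes, dtype=np.float64).reshape(-1, 4)
    out: list[list[Assignment]] = [[] for _ in strides]
    for si, (stride, anchor_set) in enumerate(zip(strides, anchors)):
        g = img_size // stride
        for mi, (cx, cy, w, h) in enumerate(gt_boxes):
            for ai, (aw, ah) in enumerate(anchor_set):
                rw, rh = w / aw, h / ah
                if max(rw, 1 / rw, rh, 1 / rh) >= ratio_thresh:
                    continue
                gx, gy = cx / stride, cy / stride
                cells = {(int(gx), int(gy))}
                fx, fy = gx % 1.0, gy % 1.0
                if fx < 0.5 and gx > 1.0:
                    cells.add((int(gx) - 1, int(gy)))
                elif fx >= 0.5 and gx < g - 1.0:
                    cells.add((int(gx) + 1, int(gy)))
                if fy < 0.5 and gy > 1.0:
                    cells.add((int(gx), int(gy) - 1))
                elif fy >= 0.5 and gy < g - 1.0:
                    cells.add((int(gx), int(gy) + 1))
                for cxi, cyi in cells:
                    if 0 <= cxi < g and 0 <= cyi < g:
                        out[si].append(Assignment(si, ai, cyi, cxi, mi))
    return out


# ---------------------------------------------------------------------------
# differentiable batch loss
# ---------------------------------------------------------------------------

def _decode_positives(view: Tensor, anchors_px, stride):
    """Decode sigmoid-offset predictions at matched cells.

    ``view``: (P, 5) raw rows; ``anchors_px``: (P, 2) anchor w,h in pixels.
    Returns (P, 4) tensor of cx, cy, w, h in pixels.  The grid offsets are
    added by the caller (they are constants per row).
    """
    xy = A.sigmoid(view[:, 0:2]) * 2.0 - 0.5
    wh = (A.sigmoid(view[:, 2:4]) * 2.0) ** 2
    return xy * stride, wh * Tensor(np.asarray(anchors_px, dtype=np.float32))


def _ciou_tensor(pred: Tensor, gt: np.ndarray):
    """Elementwise CIoU loss between (P,4) tensor boxes and constant gts."""
    gt = np.asarray(gt, dtype=np.float32)
    px, py, pw, ph = pred[:, 0], pred[:, 1], pred[:, 2], pred[:, 3]
    gx, gy = Tensor(gt[:, 0]), Tensor(gt[:, 1])
    gw, gh = Tensor(gt[:, 2]), Tensor(gt[:, 3])
    px1, px2 = px - pw * 0.5, px + pw * 0.5
    py1, py2 = py - ph * 0.5, py + ph * 0.5
    gx1, gx2 = gx - gw * 0.5, gx + gw * 0.5
    gy1, gy2 = gy - gh * 0.5, gy + gh * 0.5
    iw = A.maximum(A.minimum(px2, gx2) - A.maximum(px1, gx1), 0.0)
    ih = A.maximum(A.minimum(py2, gy2) - A.maximum(py1, gy1), 0.0)
    inter = iw * ih
    union = pw * ph + gw * gh - inter + _EPS
    i = inter / union
    d2 = (px - gx) ** 2 + (py - gy) ** 2
    cw = A.maximum(px2, gx2) - A.minimum(px1, gx1)
    ch = A.maximum(py2, gy2) - A.minimum(py1, gy1)
    c2 = cw * cw + ch * ch + _EPS
    v = (A.arctan(gw / gh) - A.arctan(pw / ph)) ** 2 * (4.0 / math.pi ** 2)
    alpha = v / ((1.0 - i) + v + _EPS)
    return 1.0 - i + d2 / c2 + alpha * v, i


def compute_loss(preds, gt_boxes_per_image, anchors=DEFAULT_ANCHORS,
                 strides=STRIDES, img_size: int = 640,
                 weights: LossWeights | None = None,
                 ratio_thresh: float = 4.0, soft_target: str = "ciou"):
    """Batch loss over raw head outputs.

    ``preds``: list of three (N, 3*5, H, W) tensors; ``gt_boxes_per_image``:
    list of (M_i, 4) pixel boxes.  Returns (total loss Tensor,
    LossBreakdown).  ``soft_target`` selects the objectness label: the
    matched prediction's CIoU (clamped to [0, 1]) or its plain IoU.
    """
    weights = weights or LossWeights()
    n_img = preds[0].shape[0]
    conf_losses = []
    loc_terms, loc_count = [], 0
    for si, (pred, stride, anchor_set) in enumerate(zip(preds, strides, anchors)):
        n, c, hgrid, wgrid = pred.shape
        na = c // OUTPUTS_PER_ANCHOR
        view = pred.reshape(n, na, OUTPUTS_PER_ANCHOR, hgrid, wgrid)
        obj_target = np.zeros((n, na, hgrid, wgrid), dtype=np.float32)
        rows, grid_off, anch, gts = [], [], [], []
        for bi in range(n_img):
            per_scale = assign_targets(gt_boxes_per_image[bi], anchors, strides,
                                       img_size, ratio_thresh)
            for a in per_scale[si]:
                rows.append((bi, a.anchor, a.gy, a.gx))
                grid_off.append((a.gx, a.gy))
                anch.append(anchor_set[a.anchor])
                gts.append(np.asarray(gt_boxes_per_image[bi])[a.gt_index])
        if rows:
            idx = tuple(np.array(rows).T)          # (bi, ai, gy, gx)
            sel = view.transpose(0, 1, 3, 4, 2)[idx]          # (P, 5)
            xy, wh = _decode_positives(sel, anch, stride)
            off = np.asarray(grid_off, dtype=np.float32) * stride
            boxes = A.concat([xy + Tensor(off), wh], axis=1)
            closs, i_plain = _ciou_tensor(boxes, np.stack(gts))
            loc_terms.append(closs.sum())
            loc_count += len(rows)
            if soft_target == "ciou":
                soft = np.clip(1.0 - closs.data, 0.0, 1.0)
            else:
                soft = np.clip(i_plain.data, 0.0, 1.0)
            obj_target[idx] = soft
        obj_logits = view[:, :, 4]
        conf_losses.append(A.bce_with_logits(obj_logits, obj_target).mean())
    k = (weights.k_small, weights.k_medium, weights.k_large)
    conf_weighted = conf_losses[0] * k[0] + conf_losses[1] * k[1] \
        + conf_losses[2] * k[2]
    if loc_count:
        loc = sum(loc_terms[1:], loc_terms[0]) * (1.0 / loc_count)
        total = conf_weighted + loc
        loc_val = float(loc.data)
    else:
        total = conf_weighted
        loc_val = 0.0
    cs, cm, cl = (float(c.data) for c in conf_losses)
    breakdown = LossBreakdown(cs, cm, cl, float(conf_weighted.data), loc_val,
                              float(total.data))
    return total, breakdown


def total_loss(conf_per_scale, loc: float,
               weights: LossWeights | None = None) -> LossBreakdown:
    """Assemble a LossBreakdown from precomputed components."""
    cw = weighted_confidence_loss(conf_per_scale, weights)
    s, m, l = conf_per_scale
    return LossBreakdown(s, m, l, cw, loc, cw + loc)


# ---------------------------------------------------------------------------
# inference decode
# ---------------------------------------------------------------------------

def decode(preds, anchors=DEFAULT_ANCHORS, strides=STRIDES):
    """Raw head outputs -> (N, total_anchors, 5) numpy [cx, cy, w, h, conf]."""
    outs = []
    for pred, stride, anchor_set in zip(preds, strides, anchors):
        p = pred.data if isinstance(pred, Tensor) else np.asarray(pred)
        n, c, h, w = p.shape
        na = c // OUTPUTS_PER_ANCHOR
        p = p.reshape(n, na, OUTPUTS_PER_ANCHOR, h, w).transpose(0, 1, 3, 4, 2)
        with np.errstate(over="ignore"):
            s = 1.0 / (1.0 + np.exp(-p))
        gy, gx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        cx = (s[..., 0] * 2.0 - 0.5 + gx) * stride
        cy = (s[..., 1] * 2.0 - 0.5 + gy) * stride
        anc = np.asarray(anchor_set, dtype=np.float32).reshape(1, na, 1, 1, 2)
        wh = (s[..., 2:4] * 2.0) ** 2 * anc
        conf = s[..., 4]
        det = np.stack([cx, cy, wh[..., 0], wh[..., 1], conf], axis=-1)
        outs.append(det.reshape(n, -1, 5))
    return np.concatenate(outs, axis=1)
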