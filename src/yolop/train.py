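"""Training runtime: schedule, loop, checkpointing, evaluation.

The schedule follows the published recipe — Adam with beta1 0.9 ("momentum
decay"), decoupled weight decay 5e-4, initial learning rate 0.01 with cosine
annealing, a 3-epoch linear warmup during which the momentum ramps from 0.8,
batch size 32, up to 500 epochs with early stopping after 50 epochs without
validation-AP improvement.  All of it is configurable so the same loop runs
a desk-scale smoke schedule on small synthetic scenes.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from . import dataio
from .assembly import (DEFAULT_ANCHORS, STRIDES, Detector, load_weights,
                       save_weights)
from .losses import BBox, LossWeights, compute_loss, decode
from .metrics import Detection, average_precision, nms
from .nn import Adam
from .nn import autograd as A


@dataclass
class TrainConfig:
    epochs: int = 500
    batch_size: int = 32
    initial_lr: float = 0.01
    momentum_decay: float = 0.9          # Adam beta1
    weight_decay: float = 0.0005         # decoupled
    warmup_epochs: int = 3
    warmup_momentum: float = 0.8
    patience: int = 50                   # epochs without val-AP improvement
    optimizer: str = "adam"
    seed: int = 0
    final_lr_fraction: float = 0.01      # cosine floor
    warmup_floor_fraction: float = 0.1
    eval_interval: int = 1
    grad_clip: float = 10.0
    img_size: int = 640

    def __post_init__(self):
        if min(self.epochs, self.batch_size, self.warmup_epochs) < 0 \
                or self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("epochs and batch size must be positive")
        if self.patience > self.epochs:
            raise ValueError("patience must not exceed the epoch budget")


def lr_schedule(epoch: int, config: TrainConfig) -> float:
    """Linear warmup to the initial rate, then cosine decay to the floor."""
    if not 0 <= epoch < config.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {config.epochs})")
    lr0 = config.initial_lr
    floor = config.warmup_floor_fraction * lr0
    final = config.final_lr_fraction * lr0
    w = config.warmup_epochs
    if epoch < w:
        return floor + (lr0 - floor) * epoch / w
    span = max(config.epochs - 1 - w, 1)
    return final + (lr0 - final) * 0.5 * (1 + math.cos(math.pi * (epoch - w) / span))


def momentum_schedule(epoch: int, config: TrainConfig) -> float:
    w = config.warmup_epochs
    if w == 0 or epoch >= w:
        return config.momentum_decay
    return config.warmup_momentum + \
        (config.momentum_decay - config.warmup_momentum) * epoch / w


def kmeans_anchors(wh: np.ndarray, n: int = 9, seed: int = 0, iters: int = 30):
    """Lloyd k-means on label (w, h); clusters grouped 3-per-scale by area."""
    wh = np.asarray(wh, dtype=np.float64).reshape(-1, 2)
    if len(wh) < n:
        wh = np.tile(wh, (int(np.ceil(n / len(wh))), 1))
    rng = np.random.default_rng(seed)
    centers = wh[rng.choice(len(wh), n, replace=False)]
    for _ in range(iters):
        d = ((wh[:, None] - centers[None]) ** 2).sum(-1)
        lab = d.argmin(1)
        for k in range(n):
            if (lab == k).any():
                centers[k] = wh[lab == k].mean(0)
    centers = centers[np.argsort(centers.prod(1))]
    return tuple(tuple(map(tuple, centers[i * 3:(i + 1) * 3]))
                 for i in range(3))


# ---------------------------------------------------------------------------
# dataset loading
# ---------------------------------------------------------------------------

def load_split(root, manifest, split: str):
    """Materialise a manifest split into (CHW float image, pixel boxes)."""
    root = Path(root)
    by_name = {r["image"]: r for r in manifest.records}
    samples = []
    for name in manifest.split[split]:
        rec = by_name[name]
        img = dataio.read_image(root / rec["image"])
        h, w = img.shape[:2]
        boxes = dataio.read_yolo_labels(root / rec["label"], w, h)
        samples.append({"image": dataio.to_chw_float(img), "boxes": boxes,
                        "record": rec})
    return samples


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def predict_image(model: Detector, image_chw: np.ndarray, anchors, strides=STRIDES,
                  conf_floor: float = 1e-3, nms_thresh: float = 0.45,
                  max_det: int = 300):
    """Forward, decode, confidence-gate and NMS one image."""
    model.eval()
    with A.no_grad():
        preds = model(image_chw[None])
    raw = decode(preds, anchors, strides)[0]
    raw = raw[raw[:, 4] >= conf_floor]
    if len(raw) > max_det:
        raw = raw[np.argsort(-raw[:, 4])[:max_det]]
    dets = [Detection(BBox(*row[:4]), float(row[4])) for row in raw
            if row[2] > 0 and row[3] > 0]
    return nms(dets, nms_thresh)


def evaluate_ap(model: Detector, samples, anchors, strides=STRIDES,
                iou_thresh: float = 0.5) -> float:
    dets, gts = [], {}
    for i, s in enumerate(samples):
        for d in predict_image(model, s["image"], anchors, strides):
            dets.append(Detection(d.box, d.confidence, i))
        gts[i] = [BBox(*b) for b in s["boxes"]]
    if not any(gts.values()):
        raise ValueError("evaluation set has no ground truths")
    return average_precision(dets, gts, iou_thresh)


# ---------------------------------------------------------------------------
# loop
# ---------------------------------------------------------------------------

class NaNLossError(RuntimeError):
    pass


def train(model: Detector, train_set, val_set, config: TrainConfig,
          out_dir, anchors=DEFAULT_ANCHORS, strides=STRIDES,
          loss_weights: LossWeights | None = None, verbose: bool = False):
    """Optimise ``model``; returns (best checkpoint path, history rows).

    Each epoch shuffles the training set, steps Adam on every batch, and
    (every ``eval_interval`` epochs) measures AP@0.5 on ``val_set``; the best
    checkpoint is kept and training stops early after ``patience`` epochs
    without improvement.  History (epoch, mean loss, val AP) goes to
    ``history.csv``.  A non-finite loss aborts with the offending batch.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.initial_lr,
               beta1=config.momentum_decay, weight_decay=config.weight_decay)
    history = []
    best_ap, best_epoch = -1.0, -1
    best_path = out_dir / "best.ckpt"
    last_path = out_dir / "last.ckpt"
    n = len(train_set)
    if n == 0:
        raise ValueError("empty training set")
    for epoch in range(config.epochs):
        opt.lr = lr_schedule(epoch, config)
        opt.beta1 = momentum_schedule(epoch, config)
        order = rng.permutation(n)
        model.train()
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            x = np.stack([train_set[i]["image"] for i in idx])
            gts = [train_set[i]["boxes"] for i in idx]
            preds = model(x)
            total, breakdown = compute_loss(
                preds, gts, anchors, strides, config.img_size, loss_weights)
            if not math.isfinite(breakdown.total):
                raise NaNLossError(
                    f"non-finite loss at epoch {epoch}, batch images "
                    f"{[int(i) for i in idx]}: {breakdown}")
            opt.zero_grad()
            total.backward()
            if config.grad_clip:
                _clip_grad_norm(opt.params, config.grad_clip)
            opt.step()
            losses.append(breakdown.total)
        val_ap = ""
        if val_set and (epoch % config.eval_interval == 0
                        or epoch == config.epochs - 1):
            val_ap = evaluate_ap(model, val_set, anchors, strides)
            if val_ap > best_ap:
                best_ap, best_epoch = val_ap, epoch
                save_weights(model, best_path, dtype="<f4")
        history.append({"epoch": epoch, "loss": float(np.mean(losses)),
                        "val_ap": val_ap})
        if verbose:
            print(f"epoch {epoch:4d} loss {np.mean(losses):.4f} "
                  f"val_ap {val_ap if val_ap != '' else '-'}")
        if val_set and epoch - best_epoch >= config.patience:
            break
    save_weights(model, last_path, dtype="<f4")
    if not best_path.exists():
        save_weights(model, best_path, dtype="<f4")
    with open(out_dir / "history.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["epoch", "loss", "val_ap"])
        writer.writeheader()
        writer.writerows(history)
    return best_path, history


def _clip_grad_norm(params, max_norm: float):
    total = math.sqrt(sum(float((p.grad ** 2).sum())
                          for p in params if p.grad is not None))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale


def smoke_train_config(epochs: int = 300, img_size: int = 96,
                       seed: int = 0) -> TrainConfig:
    """Desk-scale schedule used by the end-to-end smoke experiment."""
    return TrainConfig(epochs=epochs, batch_size=8, initial_lr=0.01,
                       warmup_epochs=3, patience=epochs, seed=seed,
                       eval_interval=10, img_size=img_size)


def smoke_dataset(n_images: int = 16, image_size: int = 96, seed: int = 0):
    """In-memory desk-scale scene set: near-tier fruit, mixed occlusion.

    Returns (samples, anchors): samples as the train loop expects them and
    anchors fitted by k-means to the generated labels.
    """
    from .synthetic import SceneSpec, SceneError, generate_scene

    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n_images):
        n = int(rng.integers(1, 4))
        occ = tuple(float(rng.uniform(0.0, 0.45)) for _ in range(n))
        for attempt in range(20):
            try:
                img, objs = generate_scene(SceneSpec(
                    image_size, "uncomplicated", n, occ, "day",
                    rng_seed=seed * 100003 + i * 37 + attempt))
                break
            except SceneError:
                continue
        else:
            raise SceneError(f"smoke scene {i} kept failing")
        boxes = np.array([[o.box.cx, o.box.cy, o.box.w, o.box.h]
                          for o in objs]).reshape(-1, 4)
        samples.append({"image": dataio.to_chw_float(img), "boxes": boxes,
                        "objects": objs})
    wh = np.concatenate([s["boxes"][:, 2:4] for s in samples])
    return samples, kmeans_anchors(wh, seed=seed)
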