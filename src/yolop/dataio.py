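"""File formats: YOLO-txt labels, detection streams, manifests, images."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .losses import BBox
from .metrics import Detection


def write_image(path, image: np.ndarray):
    iio.imwrite(Path(path), np.asarray(image, dtype=np.uint8))


def read_image(path) -> np.ndarray:
    img = iio.imread(Path(path))
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    return img[..., :3]


def to_chw_float(image: np.ndarray) -> np.ndarray:
    """HWC uint8 -> CHW float32 in [0, 1]."""
    return np.ascontiguousarray(image.transpose(2, 0, 1), dtype=np.float32) / 255.0


def write_yolo_labels(path, boxes_px: np.ndarray, img_w: int, img_h: int,
                      class_id: int = 0):
    """One object per line: ``class cx cy w h`` normalised to [0, 1]."""
    boxes_px = np.asarray(boxes_px, dtype=np.float64).reshape(-1, 4)
    lines = []
    for cx, cy, w, h in boxes_px:
        lines.append(f"{class_id} {cx / img_w:.8f} {cy / img_h:.8f} "
                     f"{w / img_w:.8f} {h / img_h:.8f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_labels(path, img_w: int, img_h: int) -> np.ndarray:
    """Returns (M, 4) pixel boxes (cx, cy, w, h); the class column is checked
    but discarded (single-class data)."""
    boxes = []
    text = Path(path).read_text()
    for line in text.splitlines():
        parts = line.split()
        if not parts:
            continue
        _, cx, cy, w, h = parts[:5]
        boxes.append((float(cx) * img_w, float(cy) * img_h,
                      float(w) * img_w, float(h) * img_h))
    return np.asarray(boxes, dtype=np.float64).reshape(-1, 4)


def write_detections(path, dets: list[Detection]):
    """Stream format: ``image_id cx cy w h confidence`` (pixel units)."""
    lines = [f"{d.image_id} {d.box.cx:.3f} {d.box.cy:.3f} {d.box.w:.3f} "
             f"{d.box.h:.3f} {d.confidence:.6f}" for d in dets]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_detections(path) -> list[Detection]:
    dets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        img_id, cx, cy, w, h, conf = line.split()
        dets.append(Detection(BBox(float(cx), float(cy), float(w), float(h)),
                              float(conf), img_id))
    return dets


def write_manifest(path, manifest):
    Path(path).write_text(yaml.safe_dump(manifest.to_dict(), sort_keys=False))


def read_manifest(path):
    from .synthetic import DatasetManifest

    return DatasetManifest.from_dict(yaml.safe_load(Path(path).read_text()))
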