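"""Synthetic orchard scenes with exact ground truth.

Real orchard imagery of this kind is not publicly distributable, so the
package ships a renderer that emulates its controlled factors:

* **background complexity tiers** — camera distance is unobservable in a
  renderer, so tiers map to on-image fruit diameter bands (uncomplicated:
  120-200 px, moderate: 60-120 px, extreme: 20-60 px at a 640 canvas) plus
  increasing leaf/branch clutter, the observable consequence of distance;
* **shade degree** — each fruit can carry a requested occlusion fraction
  K_s (shaded area / total fruit area); a leaf-like occluder is slid toward
  the fruit centre by bisection until the *measured* mask overlap is within
  +-0.02 of the request. The recorded K_s is always measured from the
  rendered masks, never assumed;
* **day / night** — night scenes get a directional luminance gradient and a
  cast-shadow band.

Boxes are amodal (full fruit extent, occluded parts included), exact ellipse
bounds.  Everything is reproducible from one integer seed; per-image seeds
are derived through ``np.random.SeedSequence``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.draw import ellipse as draw_ellipse
from skimage.filters import gaussian as gaussian_filter
from skimage.transform import rescale, resize

from .losses import BBox

logger = logging.getLogger(__name__)

TIER_DIAMETER_BANDS = {          # at a 640-pixel canvas; scaled linearly
    "uncomplicated": (120, 200),
    "moderate": (60, 120),
    "extreme": (20, 60),
}
TIER_CLUTTER = {"uncomplicated": 6, "moderate": 16, "extreme": 36}
KS_TOLERANCE = 0.02
SHADE_BOUNDS = (0.2, 0.4, 0.6)   # not/slight | medium | serious | beyond


class SceneError(RuntimeError):
    """Raised when a requested scene cannot be rendered (e.g. K_s target)."""


@dataclass
class GroundTruthObject:
    box: BBox                     # amodal, pixels
    ks: float                     # shaded / total area, measured on masks
    shade_category: str
    visible_mask_area: int
    total_mask_area: int


@dataclass
class SceneSpec:
    image_size: int = 640
    complexity_tier: str = "moderate"
    n_pears: int = 3
    occlusion: tuple = ()         # requested K_s per pear; padded with 0
    illumination: str = "day"
    rng_seed: int = 0

    def __post_init__(self):
        if self.complexity_tier not in TIER_DIAMETER_BANDS:
            raise ValueError(f"unknown tier {self.complexity_tier!r}")
        if self.illumination not in ("day", "night"):
            raise ValueError("illumination must be 'day' or 'night'")
        if any(k >= 1.0 or k < 0.0 for k in self.occlusion):
            raise ValueError("requested K_s must lie in [0, 1)")


def shade_category(ks: float) -> str:
    """Table of shade strata: [0,.2] / (.2,.4] / (.4,.6] / (.6,1]."""
    lo, mid, hi = SHADE_BOUNDS
    if ks <= lo:
        return "not_or_slight"
    if ks <= mid:
        return "medium"
    if ks <= hi:
        return "serious"
    return "beyond_scope"


def compute_shade_degree(total_mask: np.ndarray, occluder_masks) -> tuple:
    """K_s = |fruit & union(occluders)| / |fruit| and its category.

    Fruit with K_s >= 0.6 fall beyond the modelled range and are excluded
    from stratified evaluation by default.
    """
    total_mask = np.asarray(total_mask, dtype=bool)
    area = int(total_mask.sum())
    if area == 0:
        raise ValueError("empty fruit mask")
    occ = np.zeros_like(total_mask)
    for m in occluder_masks:
        if m.shape != total_mask.shape:
            raise ValueError("mask shapes differ")
        occ |= np.asarray(m, dtype=bool)
    ks = float((total_mask & occ).sum() / area)
    return ks, shade_category(ks)


# ---------------------------------------------------------------------------
# rendering primitives
# ---------------------------------------------------------------------------

def _ellipse_mask(shape, cy, cx, ry, rx, rot):
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_ellipse(cy, cx, ry, rx, shape=shape, rotation=rot)
    mask[rr, cc] = True
    return mask


def _background(rng: np.random.Generator, size: int, tier: str) -> np.ndarray:
    coarse = rng.uniform(0.0, 1.0, (8, 8, 3))
    base = resize(coarse, (size, size, 3), order=1, anti_aliasing=False)
    img = np.empty((size, size, 3), dtype=np.float32)
    img[..., 0] = 50 + 90 * base[..., 0]           # muted red/brown
    img[..., 1] = 80 + 120 * base[..., 1]          # dominant green
    img[..., 2] = 30 + 60 * base[..., 2]
    for _ in range(TIER_CLUTTER[tier]):
        kind = rng.random()
        cy, cx = rng.uniform(0, size, 2)
        if kind < 0.6:      # leaf-like ellipse
            ry, rx = rng.uniform(8, 30), rng.uniform(4, 14)
            color = np.array([rng.uniform(20, 60), rng.uniform(80, 150),
                              rng.uniform(20, 60)])
        else:               # branch-like elongated stroke
            ry, rx = rng.uniform(30, 120), rng.uniform(2, 5)
            color = np.array([rng.uniform(70, 110), rng.uniform(50, 80),
                              rng.uniform(20, 45)])
        mask = _ellipse_mask((size, size), cy, cx, ry, rx,
                             rng.uniform(-np.pi, np.pi))
        img[mask] = 0.65 * img[mask] + 0.35 * color
    return img


def _draw_pear(img, rng, cy, cx, ry, rx, rot):
    size = img.shape[0]
    mask = _ellipse_mask((size, size), cy, cx, ry, rx, rot)
    yy, xx = np.nonzero(mask)
    base = np.array([rng.uniform(170, 215), rng.uniform(185, 225),
                     rng.uniform(70, 120)])
    # radial shading towards a light point in the upper-left of the fruit
    ly, lx = cy - 0.4 * ry, cx - 0.4 * rx
    dist = np.sqrt((yy - ly) ** 2 + (xx - lx) ** 2)
    shade = 1.05 - 0.45 * dist / (dist.max() + 1e-9)
    img[yy, xx] = np.clip(base[None, :] * shade[:, None], 0, 255)
    hl = dist < 0.25 * max(ry, rx)
    img[yy[hl], xx[hl]] = np.clip(img[yy[hl], xx[hl]] + 35.0, 0, 255)
    return mask


def _place_occluder(img, rng, pear_mask, target_ks, obj_index):
    """Slide a leaf ellipse toward the fruit centre until the measured
    coverage hits ``target_ks`` within tolerance (bisection on offset)."""
    size = img.shape[0]
    area = pear_mask.sum()
    yy, xx = np.nonzero(pear_mask)
    cy, cx = yy.mean(), xx.mean()
    reach = max(np.ptp(yy), np.ptp(xx)) / 2.0
    leaf_area = max(1.6 * target_ks, 0.45) * area
    aspect = rng.uniform(1.4, 2.2)
    ry = np.sqrt(leaf_area * aspect / np.pi)
    rx = leaf_area / (np.pi * ry)
    rot = rng.uniform(-np.pi, np.pi)
    theta = rng.uniform(-np.pi, np.pi)
    d_out = reach + max(ry, rx) + 2

    def coverage(d):
        m = _ellipse_mask((size, size), cy + d * np.sin(theta),
                          cx + d * np.cos(theta), ry, rx, rot)
        return (pear_mask & m).sum() / area, m

    lo, hi = 0.0, d_out
    best_m, best_ks = None, None
    for _ in range(40):
        mid = (lo + hi) / 2.0
        ks, m = coverage(mid)
        if abs(ks - target_ks) <= KS_TOLERANCE * 0.5:
            best_m, best_ks = m, ks
            break
        if ks > target_ks:
            lo = mid        # too close -> move away
        else:
            hi = mid
        best_m, best_ks = m, ks
    if abs(best_ks - target_ks) > KS_TOLERANCE:
        raise SceneError(f"object {obj_index}: cannot reach K_s="
                         f"{target_ks:.2f} (best {best_ks:.2f})")
    color = np.array([rng.uniform(25, 60), rng.uniform(90, 150),
                      rng.uniform(25, 60)], dtype=np.float32)
    e_yy, e_xx = np.nonzero(best_m)
    grad = 0.8 + 0.4 * (e_xx - e_xx.min()) / max(1, np.ptp(e_xx))
    img[e_yy, e_xx] = np.clip(color[None, :] * grad[:, None], 0, 255)
    return best_m


def _apply_night(img, rng):
    size = img.shape[0]
    theta = rng.uniform(-np.pi, np.pi)
    yy, xx = np.mgrid[0:size, 0:size]
    proj = (np.cos(theta) * xx + np.sin(theta) * yy) / (size * np.sqrt(2))
    lum = 0.2 + 0.5 * (proj - proj.min()) / (proj.max() - proj.min())
    img *= lum[..., None]
    # cast-shadow band
    band_c = rng.uniform(0.2, 0.8) * size
    band_w = rng.uniform(0.08, 0.2) * size
    band = np.abs(np.cos(theta + np.pi / 2) * xx
                  + np.sin(theta + np.pi / 2) * yy - band_c) < band_w
    img[band] *= 0.55
    img[..., 2] *= 1.1   # cool cast from the auxiliary light
    return np.clip(img, 0, 255)


def generate_scene(spec: SceneSpec):
    """Render one scene; returns (uint8 HxWx3 image, GroundTruthObject list).

    Bit-identical for identical specs; raises :class:`SceneError` when a
    requested K_s is unattainable.
    """
    rng = np.random.default_rng(spec.rng_seed)
    size = spec.image_size
    img = _background(rng, size, spec.complexity_tier)
    lo, hi = TIER_DIAMETER_BANDS[spec.complexity_tier]
    lo, hi = lo * size / 640.0, hi * size / 640.0
    targets = list(spec.occlusion) + [0.0] * (spec.n_pears - len(spec.occlusion))

    placed = []     # (cy, cx, ry, rx, rot, radius)
    for i in range(spec.n_pears):
        diam = rng.uniform(lo, hi)
        ry = diam / 2.0
        rx = ry * rng.uniform(0.72, 0.9)
        margin = ry + 2
        if 2 * margin >= size:
            raise SceneError(f"object {i}: fruit does not fit in frame")
        for _ in range(300):
            cy = rng.uniform(margin, size - margin)
            cx = rng.uniform(margin, size - margin)
            # gap leaves room for occluding leaves between neighbours
            if all(np.hypot(cy - p[0], cx - p[1]) > 1.45 * (ry + p[5]) + 4
                   for p in placed):
                break
        else:
            raise SceneError(f"object {i}: no non-overlapping position found")
        placed.append((cy, cx, ry, rx, rng.uniform(-0.35, 0.35), ry))

    pear_masks = [
        _draw_pear(img, rng, cy, cx, ry, rx, rot)
        for cy, cx, ry, rx, rot, _ in placed
    ]
    occ_masks = []
    for i, (mask, target) in enumerate(zip(pear_masks, targets)):
        if target > 0.0:
            occ_masks.append(_place_occluder(img, rng, mask, target, i))
    if spec.illumination == "night":
        img = _apply_night(img, rng)

    objects = []
    for i, mask in enumerate(pear_masks):
        ks, cat = compute_shade_degree(mask, occ_masks)
        # a neighbour's occluder may graze this fruit; the contract is that
        # the measured value stays within tolerance of the request
        if abs(ks - targets[i]) > KS_TOLERANCE:
            raise SceneError(f"object {i}: measured K_s {ks:.3f} drifted from "
                             f"request {targets[i]:.3f}")
        yy, xx = np.nonzero(mask)
        box = BBox.from_corners(xx.min(), yy.min(), xx.max() + 1, yy.max() + 1)
        total = int(mask.sum())
        visible = total - int((mask & _union(occ_masks, mask.shape)).sum())
        objects.append(GroundTruthObject(box, ks, cat, visible, total))
    return img.astype(np.uint8), objects


def _union(masks, shape):
    out = np.zeros(shape, dtype=bool)
    for m in masks:
        out |= m
    return out


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

AUGMENT_STRATEGIES = ("hflip", "vflip", "scale", "brightness", "blur", "noise")


def augment(image: np.ndarray, boxes: np.ndarray, rng: np.random.Generator):
    """Apply three randomly chosen strategies of the six-element menu.

    Within the selection: horizontal / vertical flips fire with probability
    0.5 each; scaling uses a factor U(0.80, 0.95) (canvas padded, boxes
    rescaled); brightness U(0.35, 1.50); Gaussian blur and Gaussian noise
    with random strength.  Geometric ops transform boxes; photometric ops do
    not.  Clipped boxes with < 10% of their area left are dropped (logged).
    """
    img = np.asarray(image).astype(np.float32)
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4).copy()
    h, w = img.shape[:2]
    chosen = sorted(rng.choice(len(AUGMENT_STRATEGIES), size=3, replace=False))
    for si in chosen:
        name = AUGMENT_STRATEGIES[si]
        if name == "hflip" and rng.random() < 0.5:
            img = img[:, ::-1].copy()
            boxes[:, 0] = w - boxes[:, 0]
        elif name == "vflip" and rng.random() < 0.5:
            img = img[::-1].copy()
            boxes[:, 1] = h - boxes[:, 1]
        elif name == "scale":
            f = rng.uniform(0.80, 0.95)
            small = rescale(img, f, channel_axis=-1, anti_aliasing=True,
                            preserve_range=True)
            canvas = np.full_like(img, 114.0)
            canvas[:small.shape[0], :small.shape[1]] = small
            img = canvas
            boxes *= f
        elif name == "brightness":
            img = np.clip(img * rng.uniform(0.35, 1.50), 0, 255)
        elif name == "blur":
            img = gaussian_filter(img, sigma=rng.uniform(0.5, 2.0),
                                  channel_axis=-1, preserve_range=True)
        elif name == "noise":
            img = np.clip(img + rng.normal(0.0, rng.uniform(2.0, 12.0),
                                           img.shape), 0, 255)
    kept, dropped = [], 0
    for cx, cy, bw, bh in boxes:
        x1, y1 = max(cx - bw / 2, 0), max(cy - bh / 2, 0)
        x2, y2 = min(cx + bw / 2, w), min(cy + bh / 2, h)
        if (x2 - x1) * (y2 - y1) >= 0.1 * bw * bh and x2 > x1 and y2 > y1:
            kept.append(((x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1))
        else:
            dropped += 1
    if dropped:
        logger.debug("augment dropped %d clipped boxes", dropped)
    return img.astype(np.uint8), np.asarray(kept, dtype=np.float64).reshape(-1, 4)


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class DatasetManifest:
    records: list = field(default_factory=list)
    split: dict = field(default_factory=lambda: {"train": [], "val": []})

    def to_dict(self):
        return {"records": self.records, "split": self.split}

    @classmethod
    def from_dict(cls, d):
        return cls(records=list(d.get("records", [])),
                   split={"train": list(d["split"]["train"]),
                          "val": list(d["split"]["val"])} if "split" in d
                   else {"train": [], "val": []})


def split_dataset(manifest: DatasetManifest, ratio: float = 0.8,
                  rng: np.random.Generator | None = None) -> DatasetManifest:
    """Shuffled train/val split; |train| = round(ratio * n)."""
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie in (0, 1)")
    n = len(manifest.records)
    if n == 0:
        raise ValueError("cannot split an empty dataset")
    rng = rng or np.random.default_rng(0)
    order = rng.permutation(n)
    n_train = round(ratio * n)
    names = [r["image"] for r in manifest.records]
    manifest.split = {
        "train": [names[i] for i in order[:n_train]],
        "val": [names[i] for i in order[n_train:]],
    }
    return manifest


DEFAULT_TIER_WEIGHTS = (0.23, 0.31, 0.46)     # uncomplicated/moderate/extreme
DEFAULT_NIGHT_FRACTION = 0.30
# K_s sampler: category weights and in-category ranges (K_s < 0.6 only)
KS_MENU = (((0.0, 0.18), 0.45), ((0.22, 0.38), 0.30), ((0.42, 0.57), 0.25))


def sample_scene_spec(rng: np.random.Generator, image_size: int = 640,
                      tier_weights=DEFAULT_TIER_WEIGHTS,
                      night_fraction=DEFAULT_NIGHT_FRACTION,
                      rng_seed: int = 0) -> SceneSpec:
    tier = str(rng.choice(list(TIER_DIAMETER_BANDS), p=np.asarray(tier_weights)))
    n_pears = int(rng.integers(*{"uncomplicated": (1, 4), "moderate": (2, 6),
                                 "extreme": (4, 10)}[tier]))
    occ = []
    cat_p = np.array([w for _, w in KS_MENU])
    for _ in range(n_pears):
        ci = int(rng.choice(len(KS_MENU), p=cat_p))
        lo, hi = KS_MENU[ci][0]
        occ.append(float(rng.uniform(lo, hi)))
    illum = "night" if rng.random() < night_fraction else "day"
    return SceneSpec(image_size, tier, n_pears, tuple(occ), illum, rng_seed)


def generate_dataset(n_images: int, out_dir, seed: int = 0,
                     image_size: int = 640,
                     tier_weights=DEFAULT_TIER_WEIGHTS,
                     night_fraction=DEFAULT_NIGHT_FRACTION,
                     split_ratio: float = 0.8,
                     augment_copies: int = 0) -> DatasetManifest:
    """Render a dataset to ``out_dir`` (PNG + YOLO txt + manifest.yaml)."""
    from . import dataio

    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "labels").mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    manifest = DatasetManifest()
    for i in range(n_images):
        img_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0])
        rng = np.random.default_rng(img_seed)
        for attempt in range(10):
            spec = sample_scene_spec(rng, image_size, tier_weights,
                                     night_fraction,
                                     rng_seed=img_seed + attempt)
            try:
                img, objects = generate_scene(spec)
                break
            except SceneError:
                continue
        else:
            raise SceneError(f"image {i}: scene generation kept failing")
        name = f"scene_{i:05d}"
        img_path = out_dir / "images" / f"{name}.png"
        lab_path = out_dir / "labels" / f"{name}.txt"
        dataio.write_image(img_path, img)
        boxes = np.array([[o.box.cx, o.box.cy, o.box.w, o.box.h]
                          for o in objects]).reshape(-1, 4)
        dataio.write_yolo_labels(lab_path, boxes, image_size, image_size)
        manifest.records.append({
            "image": str(img_path.relative_to(out_dir)),
            "label": str(lab_path.relative_to(out_dir)),
            "tier": spec.complexity_tier,
            "illumination": spec.illumination,
            "objects": [{"ks": round(o.ks, 4),
                         "shade_category": o.shade_category}
                        for o in objects],
        })
        if augment_copies:
            for c in range(augment_copies):
                aimg, aboxes = augment(img, boxes, rng)
                aname = f"{name}_aug{c}"
                dataio.write_image(out_dir / "images" / f"{aname}.png", aimg)
                dataio.write_yolo_labels(out_dir / "labels" / f"{aname}.txt",
                                         aboxes, image_size, image_size)
                manifest.records.append({
                    "image": f"images/{aname}.png",
                    "label": f"labels/{aname}.txt",
                    "tier": spec.complexity_tier,
                    "illumination": spec.illumination,
                    "objects": [],
                })
    split_dataset(manifest, split_ratio, master)
    dataio.write_manifest(out_dir / "manifest.yaml", manifest)
    return manifest
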