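"""Synthetic tea-leaf disease imagery with box annotations.

Real field imagery for the five-class tea disease task (Blister Blight,
Brown Blight, Gray Blight, Red Rust, Healthy) is not redistributable, so
this module renders procedural stand-ins: a textured background, an
elliptical leaf, and class-specific lesion morphologies —

* blister blight: pale raised circular spots;
* brown blight: dark irregular blotches (angle-modulated radius);
* gray blight: desaturated patches with concentric rings;
* red rust: clusters of small orange speckles;
* healthy: no lesion, the annotation covers the whole leaf.

Lesion extent is controlled by a three-way scale: ``small`` boxes stay
under 1% of the image area, ``large`` ones cover at least 10%.  Every
image is a pure function of ``(class_id, seed, scale, size)``.

The module also provides the training-set augmentations (random
rotation, hue shift, additive noise), the 5:1:2 train/val/test split
arithmetic, and COCO-dialect JSON round-tripping.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

CLASS_NAMES = ("Blister Blight", "Brown Blight", "Gray Blight", "Red Rust", "Healthy")
HEALTHY = 4
LESION_SCALES = ("small", "medium", "large")

# per-scale bounds on the lesion box side, as a fraction of image side.
# small: area < 1% of the image; large: area >= 10% even after the
# irregular-blotch radius modulation (<= 15% shrink per axis).
_SCALE_SIDE = {"small": (0.045, 0.09), "medium": (0.14, 0.26), "large": (0.42, 0.55)}

__all__ = [
    "CLASS_NAMES",
    "LESION_SCALES",
    "AnnotatedImage",
    "DatasetManifest",
    "generate_leaf_image",
    "augment",
    "split_dataset",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
    "xyxy_to_xywh",
    "xywh_to_xyxy",
]


@dataclass
class AnnotatedImage:
    """RGB pixels plus (class_id, xyxy box) annotations.

    Boxes are 0-based, half-open ``(xmin, ymin, xmax, ymax)`` floats in
    pixel units.
    """

    pixels: np.ndarray
    annotations: list[tuple[int, tuple[float, float, float, float]]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        H, W = self.pixels.shape[:2]
        for cid, (x1, y1, x2, y2) in self.annotations:
            if not (0 <= cid < len(CLASS_NAMES)):
                raise ValueError(f"class id {cid} out of range")
            if not (0 <= x1 < x2 <= W and 0 <= y1 < y2 <= H):
                raise ValueError(f"invalid box {(x1, y1, x2, y2)} on {W}x{H} image")


@dataclass
class DatasetManifest:
    class_names: tuple[str, ...]
    records: list[dict]  # keys: image, split, image_id

    @property
    def split_counts(self) -> tuple[int, int, int]:
        c = {"train": 0, "val": 0, "test": 0}
        for r in self.records:
            c[r["split"]] += 1
        return (c["train"], c["val"], c["test"])


def _smooth_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    return ndimage.gaussian_filter(rng.standard_normal(shape), sigma)


def _ellipse_mask(S, cx, cy, ax, ay, angle) -> np.ndarray:
    yy, xx = np.mgrid[0:S, 0:S]
    ca, sa = np.cos(angle), np.sin(angle)
    xr = (xx - cx) * ca + (yy - cy) * sa
    yr = -(xx - cx) * sa + (yy - cy) * ca
    return (xr / ax) ** 2 + (yr / ay) ** 2 <= 1.0


def _mask_bbox(mask: np.ndarray) -> tuple[float, float, float, float]:
    ys, xs = np.nonzero(mask)
    return (float(xs.min()), float(ys.min()), float(xs.max() + 1), float(ys.max() + 1))


def _lesion_site(rng, S, side, leaf_c, leaf_ax):
    """Centre for a lesion box of given side, kept inside the leaf core."""
    cx0, cy0 = leaf_c
    slack_x = max(4.0, leaf_ax[0] * 0.75 - side / 2)
    slack_y = max(4.0, leaf_ax[1] * 0.75 - side / 2)
    cx = cx0 + rng.uniform(-slack_x, slack_x)
    cy = cy0 + rng.uniform(-slack_y, slack_y)
    cx = float(np.clip(cx, side / 2 + 1, S - side / 2 - 1))
    cy = float(np.clip(cy, side / 2 + 1, S - side / 2 - 1))
    return cx, cy


def generate_leaf_image(
    class_id: int,
    seed: int,
    lesion_scale: str = "medium",
    size: int = 640,
) -> AnnotatedImage:
    """Render one annotated leaf image; bit-deterministic per arguments."""
    if not 0 <= class_id < len(CLASS_NAMES):
        raise ValueError(f"invalid class id {class_id}")
    if lesion_scale not in LESION_SCALES:
        raise ValueError(f"lesion_scale must be one of {LESION_SCALES}")
    S = size
    rng = np.random.default_rng(
        np.random.SeedSequence([class_id, LESION_SCALES.index(lesion_scale), seed])
    )

    # background: brownish soil-like texture
    base = np.array([98, 82, 58], dtype=np.float32)
    tex = _smooth_noise(rng, (S, S), S / 64)[..., None]
    img = base + 28.0 * tex + 6.0 * rng.standard_normal((S, S, 1)).astype(np.float32)
    img = np.repeat(img, 3, axis=2) if img.shape[2] == 1 else img
    img += rng.uniform(-8, 8, size=3).astype(np.float32)

    # leaf: large ellipse, green with vein-like gradient
    cx, cy = S / 2 + rng.uniform(-S * 0.05, S * 0.05, 2)
    ax = S * rng.uniform(0.36, 0.44)
    ay = S * rng.uniform(0.26, 0.34)
    angle = rng.uniform(0, np.pi)
    leaf = _ellipse_mask(S, cx, cy, ax, ay, angle)
    green = np.array([52, 118, 48], dtype=np.float32) + rng.uniform(-10, 10, 3)
    shading = 1.0 + 0.25 * _smooth_noise(rng, (S, S), S / 32)
    for c in range(3):
        img[..., c] = np.where(leaf, green[c] * shading, img[..., c])

    annotations: list[tuple[int, tuple]] = []
    yy, xx = np.mgrid[0:S, 0:S]

    if class_id == HEALTHY:
        annotations.append((HEALTHY, _mask_bbox(leaf)))
    else:
        lo, hi = _SCALE_SIDE[lesion_scale]
        n_lesions = 1 if lesion_scale == "large" else int(rng.integers(1, 4))
        for _ in range(n_lesions):
            side = S * rng.uniform(lo, hi)
            lcx, lcy = _lesion_site(rng, S, side, (cx, cy), (ax, ay))
            r = side / 2.0
            dx, dy = xx - lcx, yy - lcy
            dist = np.sqrt(dx * dx + dy * dy)
            theta = np.arctan2(dy, dx)
            if class_id == 0:  # blister blight: pale raised circle
                m = dist <= r
                color = np.array([214, 206, 160], dtype=np.float32)
                soft = np.clip(1.0 - dist / r, 0, 1)[..., None]
                img = np.where(m[..., None], img * (1 - 0.85 * soft) + color * 0.85 * soft, img)
            elif class_id == 1:  # brown blight: dark irregular blotch
                k = int(rng.integers(3, 6))
                phase = rng.uniform(0, 2 * np.pi)
                rmod = r * (1.0 - 0.15 * np.abs(np.sin(k * theta + phase)))
                m = dist <= rmod
                color = np.array([88, 48, 26], dtype=np.float32)
                img = np.where(m[..., None], 0.25 * img + 0.75 * color, img)
            elif class_id == 2:  # gray blight: desaturated patch with rings
                m = dist <= r
                gray = img.mean(axis=2, keepdims=True)
                img = np.where(m[..., None], 0.25 * img + 0.75 * (gray + 60), img)
                ring = (dist <= r * 0.85) & (dist >= r * 0.7)
                ring |= (dist <= r * 0.5) & (dist >= r * 0.38)
                img = np.where(ring[..., None], img * 0.6, img)
            else:  # red rust: orange speckle cluster spanning the box
                m = np.zeros((S, S), dtype=bool)
                n_spots = max(8, int((side / S) * 120))
                sr = float(np.clip(side * 0.045, 1.0, max(1.0, r * 0.45)))
                # anchor speckles at the box corners keep the cluster extent
                pts = [
                    (lcx - r + sr, lcy - r + sr),
                    (lcx + r - sr, lcy - r + sr),
                    (lcx - r + sr, lcy + r - sr),
                    (lcx + r - sr, lcy + r - sr),
                ]
                for _ in range(n_spots):
                    pts.append(
                        (
                            lcx + rng.uniform(-r + sr, r - sr),
                            lcy + rng.uniform(-r + sr, r - sr),
                        )
                    )
                for px, py in pts:
                    m |= (xx - px) ** 2 + (yy - py) ** 2 <= sr**2
                color = np.array([205, 92, 34], dtype=np.float32)
                img = np.where(m[..., None], 0.2 * img + 0.8 * color, img)
            annotations.append((class_id, _mask_bbox(m)))

    pixels = np.clip(img, 0, 255).astype(np.uint8)
    return AnnotatedImage(
        pixels,
        annotations,
        provenance={"class_id": class_id, "seed": seed, "scale": lesion_scale},
    )


# ---------------------------------------------------------------------------
# augmentations
# ---------------------------------------------------------------------------


def _rotate_box(box, angle_deg, W, H):
    """Axis-aligned bound of a box rotated about the image centre."""
    x1, y1, x2, y2 = box
    a = np.deg2rad(angle_deg)
    # content rotated clockwise-on-screen by a ≡ corners rotated by R(+a)
    # in array coordinates (y down)
    ca, sa = np.cos(a), np.sin(a)
    cx, cy = W / 2.0, H / 2.0
    corners = np.array([[x1, y1], [x2, y1], [x1, y2], [x2, y2]], dtype=np.float64)
    rel = corners - [cx, cy]
    rot = np.stack(
        [rel[:, 0] * ca - rel[:, 1] * sa, rel[:, 0] * sa + rel[:, 1] * ca], axis=1
    ) + [cx, cy]
    nx1, ny1 = rot.min(axis=0)
    nx2, ny2 = rot.max(axis=0)
    nx1, nx2 = np.clip([nx1, nx2], 0, W)
    ny1, ny2 = np.clip([ny1, ny2], 0, H)
    if nx2 - nx1 < 1 or ny2 - ny1 < 1:
        return None
    return (float(nx1), float(ny1), float(nx2), float(ny2))


def augment(
    img: AnnotatedImage, op: str, seed: int, magnitude: float | None = None
) -> AnnotatedImage:
    """Apply one training augmentation: ``rotation`` | ``hue`` | ``noise``.

    Rotation re-maps the boxes (axis-aligned bound of the rotated corners,
    clipped); hue and noise leave boxes untouched.  ``magnitude`` fixes
    the rotation angle in degrees / hue shift in [0,1] / noise sigma,
    otherwise it is drawn from the op's default range.
    """
    from skimage import transform as sktf
    from skimage.color import hsv2rgb, rgb2hsv

    op_ids = {"rotation": 1, "hue": 2, "noise": 3}
    if op not in op_ids:
        raise ValueError(f"unknown augmentation op {op!r}")
    rng = np.random.default_rng(np.random.SeedSequence([op_ids[op], seed]))
    H, W = img.pixels.shape[:2]
    if op == "rotation":
        angle = rng.uniform(-45, 45) if magnitude is None else float(magnitude)
        if angle % 90 == 0:
            out = np.rot90(img.pixels, k=int(angle // 90) % 4, axes=(1, 0)).copy()
        else:
            rot = sktf.rotate(
                img.pixels.astype(np.float64) / 255.0, -angle, mode="edge"
            )
            out = np.clip(rot * 255.0, 0, 255).astype(np.uint8)
        anns = []
        for cid, box in img.annotations:
            nb = _rotate_box(box, angle, W, H)
            if nb is not None:
                anns.append((cid, nb))
        return AnnotatedImage(out, anns, {**img.provenance, "aug": ("rotation", angle)})
    if op == "hue":
        shift = rng.uniform(-0.12, 0.12) if magnitude is None else float(magnitude)
        hsv = rgb2hsv(img.pixels)
        hsv[..., 0] = (hsv[..., 0] + shift) % 1.0
        out = np.clip(hsv2rgb(hsv) * 255.0, 0, 255).astype(np.uint8)
        return AnnotatedImage(out, list(img.annotations), {**img.provenance, "aug": ("hue", shift)})
    if op == "noise":
        sigma = rng.uniform(3, 12) if magnitude is None else float(magnitude)
        noisy = img.pixels.astype(np.float32) + rng.normal(0, sigma, img.pixels.shape)
        out = np.clip(noisy, 0, 255).astype(np.uint8)
        return AnnotatedImage(out, list(img.annotations), {**img.provenance, "aug": ("noise", sigma)})
    raise ValueError(f"unknown augmentation op {op!r}")


# ---------------------------------------------------------------------------
# dataset split and assembly
# ---------------------------------------------------------------------------


def split_dataset(
    n_total: int,
    ratio: tuple[int, int, int] = (5, 1, 2),
    seed: int = 0,
    labels: list[int] | None = None,
) -> tuple[tuple[int, int, int], list[str]]:
    """5:1:2-style split.  Returns ``(counts, assignment)``.

    train = floor(r_t·n/Σr), val = round(r_v·n/Σr), test = remainder —
    the rounding convention that maps n=4778 under 5:1:2 to
    (2986, 597, 1195).  Assignment is a seeded permutation; when per-image
    ``labels`` are given the permutation is stratified within each class,
    keeping per-class proportions within one image of the global ratio.
    """
    if n_total < 8:
        raise ValueError("need at least 8 images to split 5:1:2")
    r = np.asarray(ratio, dtype=np.float64)
    rs = r.sum()
    n_train = int(np.floor(r[0] * n_total / rs))
    n_val = int(np.round(r[1] * n_total / rs))
    n_test = n_total - n_train - n_val
    rng = np.random.default_rng(seed)
    assignment = [""] * n_total

    def assign(indices, nt, nv):
        perm = rng.permutation(indices)
        for j, idx in enumerate(perm):
            assignment[idx] = "train" if j < nt else ("val" if j < nt + nv else "test")

    if labels is None:
        assign(np.arange(n_total), n_train, n_val)
    else:
        labels_arr = np.asarray(labels)
        classes = sorted(set(labels_arr.tolist()))
        sizes = np.array([int((labels_arr == c).sum()) for c in classes])

        def apportion(total, caps):
            """Largest-remainder allocation of ``total`` across classes,
            respecting per-class capacities."""
            ideal = caps * (total / caps.sum())
            base = np.floor(ideal).astype(int)
            short = total - base.sum()
            order = np.argsort(-(ideal - base))
            for k in order:
                if short == 0:
                    break
                if base[k] < caps[k]:
                    base[k] += 1
                    short -= 1
            return base

        per_train = apportion(n_train, sizes)
        per_val = apportion(n_val, sizes - per_train)
        for c, ct, cv in zip(classes, per_train, per_val):
            assign(np.nonzero(labels_arr == c)[0], int(ct), int(cv))
    return (n_train, n_val, n_test), assignment


def generate_dataset(
    n: int,
    seed: int = 0,
    size: int = 640,
    augment_rate: float = 0.0,
    scales: tuple[str, ...] = LESION_SCALES,
) -> DatasetManifest:
    """Class-balanced synthetic dataset with a stratified 5:1:2 split.

    ``augment_rate`` adds that fraction of extra augmented copies of
    train-split images (op drawn uniformly from rotation/hue/noise);
    ``scales`` restricts the lesion-scale pool (useful at small render
    sizes, where sub-percent lesion boxes shrink below a few pixels).
    """
    rng = np.random.default_rng(seed)
    labels = [i % len(CLASS_NAMES) for i in range(n)]
    scales = [scales[rng.integers(0, len(scales))] for _ in range(n)]
    counts, assignment = split_dataset(n, (5, 1, 2), seed=seed, labels=labels)
    records = []
    for i in range(n):
        img = generate_leaf_image(labels[i], seed=int(seed) * 100003 + i,
                                  lesion_scale=scales[i], size=size)
        records.append({"image_id": i, "image": img, "split": assignment[i]})
    if augment_rate > 0:
        train_recs = [r for r in records if r["split"] == "train"]
        n_extra = int(np.round(augment_rate * len(train_recs)))
        ops = ("rotation", "hue", "noise")
        next_id = n
        for j in range(n_extra):
            src = train_recs[int(rng.integers(0, len(train_recs)))]
            op = ops[int(rng.integers(0, 3))]
            aug = augment(src["image"], op, seed=int(rng.integers(0, 2**31 - 1)))
            records.append({"image_id": next_id, "image": aug, "split": "train"})
            next_id += 1
    return DatasetManifest(CLASS_NAMES, records)


# ---------------------------------------------------------------------------
# COCO-dialect I/O
# ---------------------------------------------------------------------------


def xyxy_to_xywh(box):
    x1, y1, x2, y2 = box
    return (x1, y1, x2 - x1, y2 - y1)


def xywh_to_xyxy(box):
    x, y, w, h = box
    return (x, y, x + w, y + h)


def write_dataset(manifest: DatasetManifest, out_dir: str) -> dict[str, str]:
    """Write PNG images plus one COCO JSON per split; returns JSON paths."""
    from PIL import Image

    img_dir = os.path.join(out_dir, "images")
    os.makedirs(img_dir, exist_ok=True)
    categories = [
        {"id": i + 1, "name": name} for i, name in enumerate(manifest.class_names)
    ]
    paths = {}
    for split in ("train", "val", "test"):
        images, annotations = [], []
        ann_id = 1
        for rec in manifest.records:
            if rec["split"] != split:
                continue
            img: AnnotatedImage = rec["image"]
            fname = f"{rec['image_id']:06d}.png"
            Image.fromarray(img.pixels).save(os.path.join(img_dir, fname))
            H, W = img.pixels.shape[:2]
            images.append(
                {"id": rec["image_id"], "file_name": fname, "width": W, "height": H}
            )
            for cid, box in img.annotations:
                x, y, w, h = xyxy_to_xywh(box)
                annotations.append(
                    {
                        "id": ann_id,
                        "image_id": rec["image_id"],
                        "category_id": cid + 1,
                        "bbox": [x, y, w, h],
                        "area": w * h,
                        "iscrowd": 0,
                    }
                )
                ann_id += 1
        coco = {"images": images, "annotations": annotations, "categories": categories}
        path = os.path.join(out_dir, f"annotations_{split}.json")
        with open(path, "w") as fh:
            json.dump(coco, fh)
        paths[split] = path
    return paths


def read_dataset(out_dir: str) -> DatasetManifest:
    """Round-trip loader for :func:`write_dataset` output."""
    from PIL import Image

    records = []
    class_names: tuple[str, ...] | None = None
    for split in ("train", "val", "test"):
        path = os.path.join(out_dir, f"annotations_{split}.json")
        if not os.path.exists(path):
            continue
        with open(path) as fh:
            coco = json.load(fh)
        class_names = tuple(c["name"] for c in sorted(coco["categories"], key=lambda c: c["id"]))
        by_img: dict[int, list] = {im["id"]: [] for im in coco["images"]}
        for ann in coco["annotations"]:
            by_img[ann["image_id"]].append(
                (ann["category_id"] - 1, xywh_to_xyxy(ann["bbox"]))
            )
        for im in coco["images"]:
            pixels = np.asarray(
                Image.open(os.path.join(out_dir, "images", im["file_name"]))
            )
            records.append(
                {
                    "image_id": im["id"],
                    "image": AnnotatedImage(pixels, by_img[im["id"]]),
                    "split": split,
                }
            )
    if class_names is None:
        raise FileNotFoundError(f"no annotation files under {out_dir}")
    records.sort(key=lambda r: r["image_id"])
    return DatasetManifest(class_names, records)
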