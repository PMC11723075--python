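"""Synthetic bone phantoms with exact ground-truth masks.

Three phantom families emulate the geometric character of the bone CT
slices the toolkit targets, without any patient data:

* ``vertebra`` — a vertebral-body ellipse plus a posterior arch (an annulus
  whose foramen is cut out) with spinous and transverse processes: a single
  markedly concave cross-section.
* ``hand``     — rows of phalanx/metacarpal capsules and carpal blobs with
  thin background gaps between bones: many small components.
* ``femur``    — one roughly convex diaphysis (a thick capsule with flared
  ends): a single simple component.

The shape grammar (ellipse/capsule unions and cutouts) is invented test
plumbing; masks are the exact analytic support of the rendered shapes.
Intensities are deterministic given ``(anatomy_tag, size, seed)``: bone
pixels get a distance-shaded bright intensity, background gets dim Gaussian
texture, everything clipped to [0, 1].

Augmentation adds zero-mean Gaussian intensity noise (masks untouched) and
dataset splitting follows the train:test:val = 8:1:1 convention.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .config import ConfigurationError

__all__ = [
    "ImageSample",
    "DatasetSplit",
    "ANATOMY_TAGS",
    "generate_phantom",
    "generate_dataset",
    "augment_gaussian",
    "split_dataset",
    "build_dataset",
    "save_samples",
    "load_manifest",
]

ANATOMY_TAGS = ("vertebra", "hand", "femur")
_TAG_ID = {t: i + 1 for i, t in enumerate(ANATOMY_TAGS)}

#: default augmentation noise level on the [0, 1] intensity scale
DEFAULT_SIGMA = 0.05


@dataclass
class ImageSample:
    """One grayscale image with its binary ground-truth mask."""

    image: np.ndarray  # float, (H, W), values in [0, 1]
    mask: np.ndarray   # uint8, (H, W), values in {0, 1}
    anatomy_tag: str
    seed: int
    augmented: bool = False

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be binary")

    @property
    def side(self) -> int:
        return self.image.shape[0]


@dataclass
class DatasetSplit:
    train: list[ImageSample]
    test: list[ImageSample]
    val: list[ImageSample]
    ratios: tuple[float, float, float] = (8.0, 1.0, 1.0)

    def __len__(self) -> int:
        return len(self.train) + len(self.test) + len(self.val)


# ---------------------------------------------------------------------------
# shape primitives on a [0, 1] x [0, 1] coordinate grid


def _grid(size: int):
    c = (np.arange(size) + 0.5) / size
    return np.meshgrid(c, c, indexing="ij")  # rows (y), cols (x)


def _ellipse(yy, xx, cy, cx, ry, rx, angle=0.0):
    dy, dx = yy - cy, xx - cx
    if angle:
        ca, sa = np.cos(angle), np.sin(angle)
        dy, dx = ca * dy - sa * dx, sa * dy + ca * dx
    return (dy / ry) ** 2 + (dx / rx) ** 2 <= 1.0


def _capsule(yy, xx, y0, x0, y1, x1, radius):
    """Points within `radius` of the segment (y0,x0)-(y1,x1)."""
    vy, vx = y1 - y0, x1 - x0
    L2 = vy * vy + vx * vx
    if L2 == 0:
        return (yy - y0) ** 2 + (xx - x0) ** 2 <= radius ** 2
    t = np.clip(((yy - y0) * vy + (xx - x0) * vx) / L2, 0.0, 1.0)
    py, px = y0 + t * vy, x0 + t * vx
    return (yy - py) ** 2 + (xx - px) ** 2 <= radius ** 2


def _vertebra_mask(size: int, rng: np.random.Generator) -> np.ndarray:
    yy, xx = _grid(size)
    j = lambda s: float(rng.uniform(-s, s))
    body = _ellipse(yy, xx, 0.40 + j(0.02), 0.5 + j(0.02),
                    0.13 + j(0.015), 0.21 + j(0.02))
    arch_cy, arch_cx = 0.62 + j(0.02), 0.5 + j(0.01)
    outer = _ellipse(yy, xx, arch_cy, arch_cx, 0.155 + j(0.01), 0.145 + j(0.01))
    foramen = _ellipse(yy, xx, arch_cy - 0.01, arch_cx, 0.085, 0.08)
    spinous = _capsule(yy, xx, arch_cy + 0.1, arch_cx, 0.88 + j(0.02),
                       arch_cx + j(0.03), 0.028)
    left = _capsule(yy, xx, arch_cy, arch_cx - 0.1, arch_cy + 0.06 + j(0.02),
                    0.16 + j(0.02), 0.025)
    right = _capsule(yy, xx, arch_cy, arch_cx + 0.1, arch_cy + 0.06 + j(0.02),
                     0.84 + j(0.02), 0.025)
    mask = (body | outer | spinous | left | right) & ~foramen
    return mask


def _hand_mask(size: int, rng: np.random.Generator) -> np.ndarray:
    yy, xx = _grid(size)
    half_gap = max(1.5 / size, 0.006)  # inter-phalanx background gap >= 1 px
    mask = np.zeros((size, size), dtype=bool)
    n_fingers = 5
    for i in range(n_fingers):
        x = 0.14 + 0.18 * i + float(rng.uniform(-0.01, 0.01))
        top = 0.08 + abs(i - 2) * 0.05 + float(rng.uniform(0, 0.02))
        bottom = 0.58 + float(rng.uniform(-0.02, 0.02))
        if size >= 96:
            n_seg = 3 if i else 2  # thumb has one fewer phalanx
        else:
            n_seg = 1  # too few pixels for clean phalanx gaps
        edges = np.linspace(top, bottom, n_seg + 1)
        r = 0.028 + float(rng.uniform(-0.003, 0.003))
        inset = r + half_gap  # round caps reach r past the segment ends
        for a, b in zip(edges[:-1], edges[1:]):
            mask |= _capsule(yy, xx, a + inset, x, b - inset, x, r)
    # carpal blobs, kept clear of the finger columns
    for k in range(3):
        cy = 0.78 + float(rng.uniform(-0.01, 0.01))
        cx = 0.25 + 0.22 * k + float(rng.uniform(-0.01, 0.01))
        mask |= _ellipse(yy, xx, cy, cx, 0.045, 0.065 + 0.01 * (k == 1))
    return mask


def _femur_mask(size: int, rng: np.random.Generator) -> np.ndarray:
    yy, xx = _grid(size)
    j = lambda s: float(rng.uniform(-s, s))
    x0, x1 = 0.5 + j(0.04), 0.5 + j(0.04)
    r = 0.075 + j(0.01)
    shaft = _capsule(yy, xx, 0.16, x0, 0.84, x1, r)
    head = _ellipse(yy, xx, 0.16, x0, 0.09 + j(0.01), 0.10 + j(0.01))
    condyle = _ellipse(yy, xx, 0.84, x1, 0.09 + j(0.01), 0.11 + j(0.01))
    return shaft | head | condyle


_SHAPES = {"vertebra": _vertebra_mask, "hand": _hand_mask, "femur": _femur_mask}


def _render(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Deterministic intensity image whose bright support is exactly `mask`."""
    dist = ndimage.distance_transform_edt(mask)
    shading = dist / max(dist.max(), 1.0)
    bone = 0.62 + 0.28 * shading + rng.normal(0.0, 0.02, mask.shape)
    background = 0.12 + rng.normal(0.0, 0.03, mask.shape)
    img = np.where(mask, bone, background)
    return np.clip(img, 0.0, 1.0)


def generate_phantom(anatomy_tag: str, size: int = 256, seed: int = 0) -> ImageSample:
    """Deterministically generate one phantom of the given anatomy."""
    if anatomy_tag not in _SHAPES:
        raise ValueError(f"anatomy_tag must be one of {ANATOMY_TAGS}, got {anatomy_tag!r}")
    if size % 32:
        raise ConfigurationError(
            f"phantom size must be divisible by 32 (four stage halvings plus "
            f"patch stride), got {size}")
    if seed < 0:
        raise ValueError("seed must be non-negative")
    rng = np.random.default_rng([_TAG_ID[anatomy_tag], size, seed])
    mask = _SHAPES[anatomy_tag](size, rng)
    image = _render(mask, rng)
    return ImageSample(image=image, mask=mask.astype(np.uint8),
                       anatomy_tag=anatomy_tag, seed=seed)


def generate_dataset(n: int, size: int = 256, seed: int = 0,
                     anatomy: str | None = None) -> list[ImageSample]:
    """n phantoms; a single anatomy, or cycling through all three."""
    tags = ANATOMY_TAGS if anatomy is None else (anatomy,)
    return [generate_phantom(tags[i % len(tags)], size, seed + i) for i in range(n)]


def augment_gaussian(samples: list[ImageSample], factor: int = 3,
                     sigma: float = DEFAULT_SIGMA, seed: int = 0) -> list[ImageSample]:
    """Each sample once unmodified plus (factor - 1) Gaussian-noise copies.

    Factor 3 triples the dataset (276 images -> 828).  Masks of noisy copies
    are bit-identical to their source's mask; noisy intensities are clipped
    to [0, 1].
    """
    if factor < 1:
        raise ConfigurationError(f"augmentation factor must be >= 1, got {factor}")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if factor == 1:
        return list(samples)
    rng = np.random.default_rng([seed, 1000003])
    out: list[ImageSample] = []
    for s in samples:
        out.append(s)
        for _ in range(factor - 1):
            noisy = np.clip(s.image + rng.normal(0.0, sigma, s.image.shape), 0.0, 1.0)
            out.append(dataclasses.replace(s, image=noisy, mask=s.mask.copy(),
                                           augmented=True))
    return out


def split_dataset(samples: list[ImageSample],
                  ratios: tuple[float, float, float] = (8.0, 1.0, 1.0),
                  seed: int = 0) -> DatasetSplit:
    """Shuffle and split into train/test/val by the given ratios.

    Test and val counts are rounded (half up) from the exact proportions;
    the remainder trains.  276 images at 8:1:1 give (220, 28, 28).
    """
    n = len(samples)
    if n < 3:
        raise ValueError(f"need at least 3 samples to split, got {n}")
    if len(ratios) != 3 or any(r <= 0 for r in ratios):
        raise ValueError(f"ratios must be three positive numbers, got {ratios}")
    total = float(sum(ratios))
    n_test = int(np.floor(n * ratios[1] / total + 0.5))
    n_val = int(np.floor(n * ratios[2] / total + 0.5))
    n_train = n - n_test - n_val
    if n_train < 1:
        raise ValueError("ratios leave no training samples")
    order = np.random.default_rng([seed, 2000003]).permutation(n)
    picked = [samples[i] for i in order]
    return DatasetSplit(train=picked[:n_train],
                        test=picked[n_train:n_train + n_test],
                        val=picked[n_train + n_test:],
                        ratios=tuple(float(r) for r in ratios))


def build_dataset(samples: list[ImageSample],
                  ratios: tuple[float, float, float] = (8.0, 1.0, 1.0),
                  factor: int = 3, sigma: float = DEFAULT_SIGMA, seed: int = 0,
                  augment_before_split: bool = False) -> DatasetSplit:
    """Split and augment.

    Default: split first, then augment only the training set (leakage-free).
    ``augment_before_split=True`` augments the whole pool first and splits
    afterwards, reproducing the augment-then-split protocol.
    """
    if augment_before_split:
        return split_dataset(augment_gaussian(samples, factor, sigma, seed),
                             ratios, seed)
    split = split_dataset(samples, ratios, seed)
    split.train = augment_gaussian(split.train, factor, sigma, seed)
    return split


# ---------------------------------------------------------------------------
# disk round-trip: 8-bit PNGs plus a JSON-lines manifest


def save_samples(split: DatasetSplit, out_dir) -> Path:
    """Write PNG images/masks and a manifest.jsonl; returns the manifest path."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.jsonl"
    with open(manifest, "w") as fh:
        idx = 0
        for split_name in ("train", "test", "val"):
            for s in getattr(split, split_name):
                stem = f"{split_name}_{idx:05d}_{s.anatomy_tag}"
                img_path = f"images/{stem}.png"
                mask_path = f"masks/{stem}.png"
                Image.fromarray(np.round(s.image * 255).astype(np.uint8), mode="L") \
                    .save(out / img_path)
                Image.fromarray((s.mask * 255).astype(np.uint8), mode="L") \
                    .save(out / mask_path)
                fh.write(json.dumps({
                    "image_path": img_path, "mask_path": mask_path,
                    "anatomy_tag": s.anatomy_tag, "split": split_name,
                    "seed": int(s.seed), "augmented": bool(s.augmented),
                }) + "\n")
                idx += 1
    return manifest


def load_manifest(manifest_path, split: str | None = None) -> list[ImageSample]:
    """Read samples back from a manifest (8-bit quantised intensities)."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    out = []
    with open(manifest_path) as fh:
        for line in fh:
            rec = json.loads(line)
            if split is not None and rec["split"] != split:
                continue
            img = np.asarray(Image.open(root / rec["image_path"]), dtype=np.float64) / 255.0
            mask = (np.asarray(Image.open(root / rec["mask_path"])) > 127).astype(np.uint8)
            out.append(ImageSample(image=img, mask=mask,
                                   anatomy_tag=rec["anatomy_tag"],
                                   seed=rec["seed"], augmented=rec["augmented"]))
    return out
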