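"""Procedural labelled image fixtures.

Renders a small dataset of shape/texture categories (circle, square,
triangle, star, cross, horizontal stripes, checkerboard, ring) with seeded
within-class variation in position, scale and colour. The dataset plays the
role of a desk-scale natural-image corpus: enough categorical structure to
train the fixture classifier to high accuracy and the fixture generator to
produce class-recognisable images, while remaining fully reproducible from a
single integer seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from .image import read_png, write_png

DEFAULT_CATEGORIES = (
    "circle",
    "square",
    "triangle",
    "star",
    "cross",
    "horizontal-stripes",
    "checkerboard",
    "ring",
)

_BASE_FG = np.array([0.9, 0.9, 0.9])
_BASE_BG = np.array([0.12, 0.12, 0.12])


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one procedural dataset.

    position/scale jitter are fractions of the image side and of the base
    shape size respectively; colour_jitter in [0, 1] interpolates between the
    fixed high-contrast base palette (0) and fully random contrasting
    colours (1). noise_sigma is i.i.d. Gaussian pixel noise, clipped to the
    canonical range.
    """

    categories: tuple[str, ...] = DEFAULT_CATEGORIES
    image_size: int = 32
    samples_per_class: int = 10
    seed: int = 0
    position_jitter: float = 0.15
    scale_jitter: float = 0.20
    colour_jitter: float = 1.0
    noise_sigma: float = 0.01

    def __post_init__(self) -> None:
        if len(set(self.categories)) != len(self.categories):
            raise ValueError("categories must be unique")
        if len(self.categories) == 0:
            raise ValueError("need at least one category")
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if self.samples_per_class < 1:
            raise ValueError("samples_per_class must be >= 1")

    @property
    def num_classes(self) -> int:
        return len(self.categories)


@dataclass
class LabelledImageSet:
    images: np.ndarray  # (N, H, W, 3) canonical range
    labels: np.ndarray  # (N,) int category indices
    spec: FixtureSpec

    def __post_init__(self) -> None:
        n = self.spec.num_classes * self.spec.samples_per_class
        if len(self.images) != n or len(self.labels) != n:
            raise ValueError("images/labels length inconsistent with spec")
        if self.labels.min() < 0 or self.labels.max() >= self.spec.num_classes:
            raise ValueError("label out of range")

    def __len__(self) -> int:
        return len(self.images)


# ---------------------------------------------------------------------------
# analytic masks


def _polygon_sdf(px: np.ndarray, py: np.ndarray, verts: np.ndarray) -> np.ndarray:
    """Signed distance from grid points to a simple polygon (negative inside)."""
    d = np.full(px.shape, np.inf)
    sign = np.ones(px.shape)
    n = len(verts)
    j = n - 1
    for i in range(n):
        vix, viy = verts[i]
        vjx, vjy = verts[j]
        ex, ey = vjx - vix, vjy - viy
        wx, wy = px - vix, py - viy
        t = np.clip((wx * ex + wy * ey) / (ex * ex + ey * ey), 0.0, 1.0)
        bx, by = wx - t * ex, wy - t * ey
        d = np.minimum(d, np.hypot(bx, by))
        c1 = py >= viy
        c2 = py < vjy
        c3 = ex * wy > ey * wx
        allc = c1 & c2 & c3
        nonec = ~c1 & ~c2 & ~c3
        sign = np.where(allc | nonec, -sign, sign)
        j = i
    return sign * d


def _star_vertices(cx: float, cy: float, r_out: float, r_in: float) -> np.ndarray:
    angles = -np.pi / 2 + np.arange(10) * np.pi / 5
    radii = np.where(np.arange(10) % 2 == 0, r_out, r_in)
    return np.stack([cx + radii * np.cos(angles), cy + radii * np.sin(angles)], axis=1)


def _triangle_vertices(cx: float, cy: float, r: float) -> np.ndarray:
    angles = -np.pi / 2 + np.arange(3) * 2 * np.pi / 3
    return np.stack([cx + r * np.cos(angles), cy + r * np.sin(angles)], axis=1)


def _box_sdf(dx: np.ndarray, dy: np.ndarray, hw: float, hh: float) -> np.ndarray:
    qx, qy = np.abs(dx) - hw, np.abs(dy) - hh
    outside = np.hypot(np.maximum(qx, 0.0), np.maximum(qy, 0.0))
    inside = np.minimum(np.maximum(qx, qy), 0.0)
    return outside + inside


def shape_mask(category_name: str, size: int, cx: float, cy: float,
               scale: float, phase: float = 0.0) -> np.ndarray:
    """Soft coverage mask in [0, 1] for one shape instance.

    `scale` multiplies the base shape radius (0.30 * size); `phase` shifts
    periodic textures. The edge is antialiased over ~1 pixel.
    """
    yy, xx = np.mgrid[0:size, 0:size].astype(float) + 0.5
    dx, dy = xx - cx, yy - cy
    r = 0.30 * size * scale

    if category_name == "circle":
        d = np.hypot(dx, dy) - r
    elif category_name == "square":
        d = _box_sdf(dx, dy, r, r)
    elif category_name == "triangle":
        d = _polygon_sdf(xx, yy, _triangle_vertices(cx, cy, 1.25 * r))
    elif category_name == "star":
        d = _polygon_sdf(xx, yy, _star_vertices(cx, cy, 1.25 * r, 0.55 * r))
    elif category_name == "cross":
        d = np.minimum(_box_sdf(dx, dy, r, 0.35 * r), _box_sdf(dx, dy, 0.35 * r, r))
    elif category_name == "ring":
        d = np.maximum(np.hypot(dx, dy) - r, 0.55 * r - np.hypot(dx, dy))
    elif category_name == "horizontal-stripes":
        period = max(4.0, 0.25 * size * scale)
        wave = np.sin(2 * np.pi * (yy - phase) / period)
        return np.clip(0.5 + wave * period / (2 * np.pi), 0.0, 1.0)
    elif category_name == "checkerboard":
        period = max(4.0, 0.30 * size * scale)
        sx = np.clip(0.5 + np.sin(2 * np.pi * (xx - phase) / period) * period / (2 * np.pi), 0, 1)
        sy = np.clip(0.5 + np.sin(2 * np.pi * (yy - phase) / period) * period / (2 * np.pi), 0, 1)
        return sx * (1 - sy) + (1 - sx) * sy
    else:
        raise ValueError(f"unknown category name {category_name!r}")
    return np.clip(0.5 - d, 0.0, 1.0)


# ---------------------------------------------------------------------------
# rendering


def _instance_rng(spec_seed: int, category: int, index: int) -> np.random.Generator:
    entropy = (spec_seed & 0xFFFFFFFF, category & 0xFFFFFFFF, index & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _contrasting_colours(rng: np.random.Generator, jitter: float) -> tuple[np.ndarray, np.ndarray]:
    bg = rng.uniform(0.0, 1.0, size=3)
    fg = rng.uniform(0.0, 1.0, size=3)
    while np.abs(fg - bg).sum() < 0.75:  # guarantee visible shapes
        fg = rng.uniform(0.0, 1.0, size=3)
    fg = _BASE_FG + jitter * (fg - _BASE_FG)
    bg = _BASE_BG + jitter * (bg - _BASE_BG)
    return fg, bg


def render_shape_image(category: int, spec: FixtureSpec, instance_seed: int) -> np.ndarray:
    """Render one seeded instance of a category; deterministic in all args."""
    if not 0 <= category < spec.num_classes:
        raise ValueError(f"category {category} out of range [0, {spec.num_classes})")
    rng = _instance_rng(spec.seed, category, instance_seed)
    size = spec.image_size

    fg, bg = _contrasting_colours(rng, spec.colour_jitter)
    jx, jy = rng.uniform(-1.0, 1.0, size=2) * spec.position_jitter * size
    scale = 1.0 + rng.uniform(-1.0, 1.0) * spec.scale_jitter
    phase = rng.uniform(0.0, size) * (1.0 if spec.position_jitter > 0 else 0.0)

    mask = shape_mask(spec.categories[category], size, size / 2 + jx, size / 2 + jy,
                      scale, phase)
    img = mask[:, :, None] * fg + (1.0 - mask[:, :, None]) * bg
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_dataset(spec: FixtureSpec) -> LabelledImageSet:
    """Balanced dataset: samples_per_class instances of every category."""
    images, labels = [], []
    for cat in range(spec.num_classes):
        for idx in range(spec.samples_per_class):
            images.append(render_shape_image(cat, spec, idx))
            labels.append(cat)
    return LabelledImageSet(np.stack(images), np.asarray(labels, dtype=int), spec)


def holdout_split(dataset: LabelledImageSet, test_fraction: float = 0.2
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic per-class 80/20 split (last fraction of each class held out)."""
    train_idx, test_idx = [], []
    n_test = max(1, int(round(dataset.spec.samples_per_class * test_fraction)))
    for cat in range(dataset.spec.num_classes):
        idx = np.flatnonzero(dataset.labels == cat)
        test_idx.extend(idx[-n_test:])
        train_idx.extend(idx[:-n_test])
    tr, te = np.asarray(train_idx), np.asarray(test_idx)
    return dataset.images[tr], dataset.labels[tr], dataset.images[te], dataset.labels[te]


# ---------------------------------------------------------------------------
# persistence


def save_dataset(dataset: LabelledImageSet, out_dir: str | os.PathLike) -> None:
    """Write PNG files plus a JSON manifest (filename, label, seed)."""
    os.makedirs(out_dir, exist_ok=True)
    entries = []
    counters: dict[int, int] = {}
    for i, (img, label) in enumerate(zip(dataset.images, dataset.labels)):
        idx = counters.get(int(label), 0)
        counters[int(label)] = idx + 1
        name = f"{dataset.spec.categories[label]}_{idx:04d}.png"
        write_png(os.path.join(out_dir, name), img)
        entries.append({"filename": name, "label": int(label), "seed": idx})
    manifest = {
        "categories": list(dataset.spec.categories),
        "image_size": dataset.spec.image_size,
        "samples_per_class": dataset.spec.samples_per_class,
        "seed": dataset.spec.seed,
        "images": entries,
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)


def load_dataset(in_dir: str | os.PathLike) -> LabelledImageSet:
    with open(os.path.join(in_dir, "manifest.json")) as fh:
        manifest = json.load(fh)
    spec = FixtureSpec(
        categories=tuple(manifest["categories"]),
        image_size=manifest["image_size"],
        samples_per_class=manifest["samples_per_class"],
        seed=manifest["seed"],
    )
    images = np.stack([read_png(os.path.join(in_dir, e["filename"]))
                       for e in manifest["images"]])
    labels = np.asarray([e["label"] for e in manifest["images"]], dtype=int)
    return LabelledImageSet(images, labels, spec)
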