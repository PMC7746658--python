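"""Deterministic synthetic leaf-image datasets and labeled-directory I/O.

The generator renders a filled-ellipse "leaf" on a textured background with
blurred elliptical lesions.  Class identity is encoded in controllable
visual features — base leaf hue, lesion count, lesion aspect ratio and
lesion color — whose strength is a single knob in [0, 1]:

* ``feature_strength = 0``: every class draws from the identical image
  distribution (same pixels for the same draw seed, whatever the label);
* ``feature_strength = 1``: class hues are spread across the color circle
  and lesion geometry is fully class-keyed, so a small classifier separates
  classes easily.

Determinism: each image is a pure function of ``(spec.seed, draw_seed)``
via a counter-based seed scheme (``SeedSequence(spec.seed,
spawn_key=(draw_seed,))``), so parallel or out-of-order generation yields
bit-identical datasets.  Images are stored as 8-bit RGB in [0, 255] and
converted to [-1, 1] only at network input.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
from matplotlib.colors import hsv_to_rgb
from PIL import Image, UnidentifiedImageError
from scipy.ndimage import gaussian_filter

__all__ = ["LeafDatasetSpec", "LabeledImageSet", "generate_leaf_image",
           "generate_dataset", "split_labeled_directory",
           "load_labeled_directory", "save_labeled_directory", "split_counts"]


@dataclass(frozen=True)
class LeafDatasetSpec:
    """Recipe for a synthetic leaf dataset (identical spec ⇒ identical data)."""

    n_classes: int = 38
    n_per_class_train: int = 10
    n_per_class_test: int = 10
    image_size: int = 32
    feature_strength: float = 1.0
    seed: int = 0
    #: optional per-class training counts (unbalanced datasets); overrides
    #: ``n_per_class_train`` when given
    train_counts: Optional[Tuple[int, ...]] = None

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if self.n_per_class_train < 1 or self.n_per_class_test < 1:
            raise ValueError("per-class counts must be >= 1")
        if not 0.0 <= self.feature_strength <= 1.0:
            raise ValueError("feature_strength must lie in [0, 1]")
        if self.train_counts is not None:
            if len(self.train_counts) != self.n_classes:
                raise ValueError("train_counts must have one entry per class")
            if any(c < 1 for c in self.train_counts):
                raise ValueError("train_counts entries must be >= 1")

    def per_class_train(self) -> List[int]:
        if self.train_counts is not None:
            return list(self.train_counts)
        return [self.n_per_class_train] * self.n_classes

    def to_dict(self) -> dict:
        d = {"n_classes": self.n_classes,
             "n_per_class_train": self.n_per_class_train,
             "n_per_class_test": self.n_per_class_test,
             "image_size": self.image_size,
             "feature_strength": self.feature_strength,
             "seed": self.seed}
        if self.train_counts is not None:
            d["train_counts"] = list(self.train_counts)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LeafDatasetSpec":
        d = dict(d)
        if d.get("train_counts") is not None:
            d["train_counts"] = tuple(d["train_counts"])
        return cls(**d)


@dataclass
class LabeledImageSet:
    """A stack of same-shape 8-bit RGB images with integer class labels."""

    images: np.ndarray          # (N, H, W, 3) uint8
    labels: np.ndarray          # (N,) int64
    class_names: List[str]

    def __post_init__(self):
        self.images = np.ascontiguousarray(self.images)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.images.ndim != 4 or self.images.shape[-1] != 3:
            raise ValueError("images must be (N, H, W, 3)")
        if self.images.dtype != np.uint8:
            raise ValueError("images must be uint8 in [0, 255]")
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels disagree in length")
        if len(self.labels) and (self.labels.min() < 0
                                 or self.labels.max() >= len(self.class_names)):
            raise ValueError("label outside [0, n_classes)")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def image_size(self) -> int:
        return self.images.shape[1]

    def subset(self, idx) -> "LabeledImageSet":
        return LabeledImageSet(self.images[idx], self.labels[idx], self.class_names)

    def concat(self, other: "LabeledImageSet") -> "LabeledImageSet":
        if other.class_names != self.class_names:
            raise ValueError("class maps differ")
        return LabeledImageSet(np.concatenate([self.images, other.images]),
                               np.concatenate([self.labels, other.labels]),
                               self.class_names)

    def to_float(self) -> np.ndarray:
        """Scale pixels to [-1, 1] (the tanh-generator convention)."""
        return self.images.astype(np.float64) / 127.5 - 1.0

    @staticmethod
    def from_float(arr: np.ndarray, labels: np.ndarray,
                   class_names: List[str]) -> "LabeledImageSet":
        img = np.clip((np.asarray(arr) + 1.0) * 127.5, 0, 255)
        return LabeledImageSet(np.round(img).astype(np.uint8), labels, class_names)


# -- rendering -------------------------------------------------------------

def _class_features(class_index: int, spec: LeafDatasetSpec) -> dict:
    """Deterministic class-keyed rendering parameters.

    At strength 0 everything collapses to the class-independent base values.
    """
    s = spec.feature_strength
    k, K = class_index, spec.n_classes
    base_hue = 0.30                               # mid green
    hue = (base_hue + s * 0.85 * k / K) % 1.0
    lesion_count = 2 + int(round(s * (k % 4)))
    aspect = 1.0 + s * 0.8 * ((k % 3) - 1)        # tall / round / wide
    lesion_hue = (0.08 + s * 0.03 * ((k * 7) % 5 - 2)) % 1.0
    return {"hue": hue, "lesion_count": lesion_count,
            "aspect": aspect, "lesion_hue": lesion_hue}


def generate_leaf_image(class_index: int, spec: LeafDatasetSpec,
                        draw_seed: int) -> np.ndarray:
    """Render one leaf image; a pure function of (class, spec, draw_seed).

    The random stream is keyed on ``(spec.seed, draw_seed)`` only, so with
    ``feature_strength = 0`` two classes given the same draw seed produce
    bit-identical pixels — the label carries no information by construction.
    """
    if not 0 <= class_index < spec.n_classes:
        raise ValueError(
            f"class_index {class_index} out of range [0, {spec.n_classes})")
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(int(draw_seed),)))
    S = spec.image_size
    feats = _class_features(class_index, spec)

    yy, xx = np.mgrid[0:S, 0:S] / (S - 1.0)

    # textured background: warm gray + smoothed noise
    bg_val = 0.72 + 0.06 * rng.normal()
    texture = gaussian_filter(rng.normal(0, 1, (S, S)), sigma=S / 16.0)
    texture /= max(np.abs(texture).max(), 1e-9)
    bg = np.clip(bg_val + 0.05 * texture, 0, 1)[..., None] * \
        np.array([1.0, 0.97, 0.92])

    # leaf ellipse with jittered radii and orientation
    theta = rng.uniform(0, math.pi)
    ra = 0.38 + 0.03 * rng.normal()
    rb = 0.27 + 0.03 * rng.normal()
    ct, st = math.cos(theta), math.sin(theta)
    u = (xx - 0.5) * ct + (yy - 0.5) * st
    v = -(xx - 0.5) * st + (yy - 0.5) * ct
    leaf_mask = ((u / ra) ** 2 + (v / rb) ** 2 <= 1.0).astype(np.float64)
    leaf_soft = gaussian_filter(leaf_mask, sigma=0.6)

    hue = (feats["hue"] + 0.010 * rng.normal()) % 1.0
    sat = np.clip(0.55 + 0.08 * rng.normal(), 0, 1)
    val = np.clip(0.45 + 0.08 * rng.normal(), 0, 1)
    leaf_rgb = hsv_to_rgb([hue, sat, val])
    # per-pixel venation speckle
    speckle = gaussian_filter(rng.normal(0, 1, (S, S)), sigma=1.0)
    leaf_col = np.clip(leaf_rgb[None, None, :] + 0.04 * speckle[..., None], 0, 1)

    img = bg * (1 - leaf_soft[..., None]) + leaf_col * leaf_soft[..., None]

    # blurred elliptical lesions, class-keyed count / aspect / color
    lesion_rgb = hsv_to_rgb([feats["lesion_hue"],
                             np.clip(0.7 + 0.05 * rng.normal(), 0, 1), 0.35])
    aspect = feats["aspect"]
    for _ in range(feats["lesion_count"]):
        # polar placement keeps lesions on the leaf
        r = math.sqrt(rng.uniform(0, 0.55))
        ang = rng.uniform(0, 2 * math.pi)
        cu, cv = r * ra * math.cos(ang), r * rb * math.sin(ang)
        rad = rng.uniform(0.05, 0.09)
        m = (((u - cu) * aspect / rad) ** 2
             + ((v - cv) / (rad * aspect)) ** 2 <= 1.0).astype(np.float64)
        m = gaussian_filter(m, sigma=S / 40.0) * leaf_mask
        img = img * (1 - 0.85 * m[..., None]) \
            + lesion_rgb[None, None, :] * 0.85 * m[..., None]

    return np.round(np.clip(img, 0, 1) * 255).astype(np.uint8)


def _default_class_names(n: int) -> List[str]:
    return [f"class_{i:02d}" for i in range(n)]


def generate_dataset(spec: LeafDatasetSpec
                     ) -> Tuple[LabeledImageSet, LabeledImageSet]:
    """Generate balanced (or ``train_counts``-shaped) train/test splits.

    Draw seeds are a global counter (train first, then test), so the two
    splits never share an image and regeneration is bit-identical.
    """
    names = _default_class_names(spec.n_classes)
    train_counts = spec.per_class_train()

    def render(pairs):
        if not pairs:
            return LabeledImageSet(
                np.zeros((0, spec.image_size, spec.image_size, 3), np.uint8),
                np.zeros(0, np.int64), names)
        imgs = np.stack([generate_leaf_image(c, spec, ds) for c, ds in pairs])
        labels = np.array([c for c, _ in pairs], dtype=np.int64)
        return LabeledImageSet(imgs, labels, names)

    counter = 0
    train_pairs = []
    for c, n in enumerate(train_counts):
        for _ in range(n):
            train_pairs.append((c, counter))
            counter += 1
    test_pairs = []
    for c in range(spec.n_classes):
        for _ in range(spec.n_per_class_test):
            test_pairs.append((c, counter))
            counter += 1
    return render(train_pairs), render(test_pairs)


# -- directory trees -------------------------------------------------------

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}


def save_labeled_directory(dataset: LabeledImageSet, root, spec=None,
                           split_name: str = "all") -> None:
    """Write a class-per-subdirectory PNG tree plus a ``dataset.json`` manifest."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    membership = {}
    for i, (img, lab) in enumerate(zip(dataset.images, dataset.labels)):
        cdir = root / dataset.class_names[lab]
        cdir.mkdir(exist_ok=True)
        fname = f"{split_name}_{i:05d}.png"
        Image.fromarray(img).save(cdir / fname)
        membership[f"{dataset.class_names[lab]}/{fname}"] = split_name
    manifest = {"class_names": dataset.class_names,
                "split": membership,
                "spec": spec.to_dict() if spec is not None else None}
    mpath = root / "dataset.json"
    if mpath.exists():
        old = json.loads(mpath.read_text())
        old["split"].update(membership)
        manifest = old
    mpath.write_text(json.dumps(manifest, indent=1))


def load_labeled_directory(root, skip_unreadable: bool = False) -> LabeledImageSet:
    """Load a class-per-subdirectory image tree (classes sorted by name)."""
    root = Path(root)
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not class_dirs:
        raise ValueError(f"no class subdirectories under {root}")
    names = [p.name for p in class_dirs]
    imgs, labels = [], []
    for lab, cdir in enumerate(class_dirs):
        files = sorted(p for p in cdir.iterdir()
                       if p.suffix.lower() in _IMAGE_SUFFIXES)
        if not files:
            raise ValueError(f"class directory {cdir} holds no images")
        for f in files:
            try:
                with Image.open(f) as im:
                    imgs.append(np.asarray(im.convert("RGB")))
            except (UnidentifiedImageError, OSError) as e:
                if skip_unreadable:
                    warnings.warn(f"skipping unreadable image {f}: {e}")
                    continue
                raise ValueError(f"unreadable image file {f}: {e}") from e
            labels.append(lab)
    shapes = {im.shape for im in imgs}
    if len(shapes) > 1:
        raise ValueError(f"images disagree in shape: {sorted(shapes)}")
    return LabeledImageSet(np.stack(imgs), np.array(labels), names)


def split_counts(n: int, train_fraction: float) -> Tuple[int, int]:
    """Per-class split rule: floor(fraction·n) train, but at least one image
    on each side (test side only when fraction < 1)."""
    if not 0.0 < train_fraction <= 1.0:
        raise ValueError("train_fraction must lie in (0, 1]")
    n_train = max(1, math.floor(train_fraction * n))
    if train_fraction < 1.0 and n >= 2:
        n_train = min(n_train, n - 1)
    return n_train, n - n_train


def split_labeled_directory(root, train_fraction: float, seed: int,
                            skip_unreadable: bool = False
                            ) -> Tuple[LabeledImageSet, LabeledImageSet]:
    """Stratified random split of an image tree into train/test partitions."""
    data = load_labeled_directory(root, skip_unreadable=skip_unreadable)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for lab in range(data.n_classes):
        idx = np.flatnonzero(data.labels == lab)
        rng.shuffle(idx)
        n_train, _ = split_counts(len(idx), train_fraction)
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    if not test_idx:
        warnings.warn("train_fraction leaves an empty test set")
    return data.subset(np.array(train_idx, dtype=np.int64)), \
        data.subset(np.array(test_idx, dtype=np.int64))
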