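"""Classic per-epoch image augmentation (geometric + photometric).

Semantics follow the conventions of the common image-generator tooling the
full-scale protocol used:

* rotation is sampled uniformly in [-range, +range] degrees;
* "0.3 width shift" means a uniform pixel shift in [-0.3, +0.3] × width
  (likewise height);
* "0.3 zoom" means a scale factor uniform in [0.7, 1.3];
* flips are fair coin flips when enabled;
* out-of-frame pixels are filled per ``fill_mode`` (default "nearest").

Photometric jitter (brightness / contrast / sharpness enhancement factors)
defaults to the identity range (1, 1) — i.e. off — since the four-regime
protocol lists only the geometric transforms; the factors use the classic
PIL enhancement semantics documented on :func:`photometric_transform`.

Axis-aligned cases (pure flips, rotations by multiples of 90° with no
shift/zoom) are computed exactly; arbitrary angles use bilinear resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Tuple

import numpy as np
from PIL import Image, ImageEnhance
from scipy import ndimage

from .data import LabeledImageSet

__all__ = ["AugmentConfig", "sample_params", "geometric_transform",
           "photometric_transform", "augment_batch", "contact_sheet"]

_FILL_MODES = {"nearest", "constant", "reflect", "wrap"}


@dataclass(frozen=True)
class AugmentConfig:
    """Stochastic augmentation ranges (defaults = the four-regime protocol)."""

    rotation_range: float = 360.0
    width_shift_range: float = 0.3
    height_shift_range: float = 0.3
    zoom_range: float = 0.3
    horizontal_flip: bool = True
    vertical_flip: bool = True
    brightness_jitter: Tuple[float, float] = (1.0, 1.0)
    contrast_jitter: Tuple[float, float] = (1.0, 1.0)
    sharpness_jitter: Tuple[float, float] = (1.0, 1.0)
    fill_mode: str = "nearest"
    seed: int = 0

    def __post_init__(self):
        for name in ("rotation_range", "width_shift_range",
                     "height_shift_range", "zoom_range"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.zoom_range >= 1.0:
            raise ValueError("zoom_range must be < 1 (scale stays positive)")
        for name in ("brightness_jitter", "contrast_jitter", "sharpness_jitter"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name} must satisfy 0 < lo <= hi")
        if self.fill_mode not in _FILL_MODES:
            raise ValueError(f"fill_mode must be one of {sorted(_FILL_MODES)}")

    @property
    def photometric_active(self) -> bool:
        return any(getattr(self, n) != (1.0, 1.0) for n in
                   ("brightness_jitter", "contrast_jitter", "sharpness_jitter"))

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("brightness_jitter", "contrast_jitter", "sharpness_jitter"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AugmentConfig":
        d = dict(d)
        for k in ("brightness_jitter", "contrast_jitter", "sharpness_jitter"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def identity(self) -> bool:
        return (self.rotation_range == 0 and self.width_shift_range == 0
                and self.height_shift_range == 0 and self.zoom_range == 0
                and not self.horizontal_flip and not self.vertical_flip
                and not self.photometric_active)


def sample_params(config: AugmentConfig, rng: np.random.Generator) -> dict:
    """Draw one set of transform parameters (fixed sampling order)."""
    return {
        "rotation_deg": rng.uniform(-config.rotation_range, config.rotation_range)
                        if config.rotation_range else 0.0,
        "shift_x": rng.uniform(-config.width_shift_range, config.width_shift_range)
                   if config.width_shift_range else 0.0,
        "shift_y": rng.uniform(-config.height_shift_range, config.height_shift_range)
                   if config.height_shift_range else 0.0,
        "zoom": rng.uniform(1 - config.zoom_range, 1 + config.zoom_range)
                if config.zoom_range else 1.0,
        "hflip": bool(rng.integers(2)) if config.horizontal_flip else False,
        "vflip": bool(rng.integers(2)) if config.vertical_flip else False,
        "brightness": rng.uniform(*config.brightness_jitter),
        "contrast": rng.uniform(*config.contrast_jitter),
        "sharpness": rng.uniform(*config.sharpness_jitter),
        "fill_mode": config.fill_mode,
    }


def geometric_transform(image: np.ndarray, params: dict) -> np.ndarray:
    """Apply flips, rotation, zoom and shift to one uint8 HWC image.

    ``shift_x``/``shift_y`` are fractions of width/height; ``zoom`` > 1
    magnifies.  Output shape equals input shape.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an HWC RGB image")
    rot = float(params.get("rotation_deg", 0.0))
    zoom = float(params.get("zoom", 1.0))
    sx = float(params.get("shift_x", 0.0)) * img.shape[1]
    sy = float(params.get("shift_y", 0.0)) * img.shape[0]
    if zoom <= 0:
        raise ValueError("zoom factor must be positive (empty crop otherwise)")
    if params.get("hflip"):
        img = img[:, ::-1]
    if params.get("vflip"):
        img = img[::-1]
    if rot % 90 == 0 and zoom == 1.0 and sx == 0.0 and sy == 0.0:
        return np.ascontiguousarray(np.rot90(img, int(rot // 90) % 4))
    theta = np.deg2rad(rot)
    c, s = np.cos(theta), np.sin(theta)
    # output pixel o maps to input A @ o + b (rows, cols); rotation about the
    # image center, then zoom, then pixel shift (sy rows, sx cols)
    A = np.array([[c, -s], [s, c]]) / zoom
    center = (np.array(img.shape[:2]) - 1) / 2.0
    b = center - A @ (center + np.array([sy, sx]))
    mode = params.get("fill_mode", "nearest")
    out = np.empty_like(img)
    for ch in range(3):
        out[..., ch] = np.clip(np.round(ndimage.affine_transform(
            img[..., ch].astype(np.float64), A, offset=b, order=1,
            mode=mode, cval=0.0)), 0, 255).astype(np.uint8)
    return out


def photometric_transform(image: np.ndarray, params: dict) -> np.ndarray:
    """Brightness / contrast / sharpness enhancement of one uint8 image.

    Classic enhancement semantics: with factor f,

    * brightness: ``out = round(f · pix)`` (f = 0 gives an all-black image);
    * contrast: ``out = round(m + f · (pix − m))`` where m is the rounded
      mean of the grayscale (ITU-R 601 luma) image;
    * sharpness: blend with a 3×3 smoothing kernel (f = 0 blurred,
      1 identity, 2 sharpened).

    All outputs are clipped to [0, 255]; factor 1 for all three is the
    identity.
    """
    for key in ("brightness", "contrast", "sharpness"):
        if params.get(key, 1.0) < 0:
            raise ValueError(f"{key} factor must be non-negative")
    im = Image.fromarray(np.asarray(image))
    b = params.get("brightness", 1.0)
    c = params.get("contrast", 1.0)
    s = params.get("sharpness", 1.0)
    if b != 1.0:
        im = ImageEnhance.Brightness(im).enhance(b)
    if c != 1.0:
        im = ImageEnhance.Contrast(im).enhance(c)
    if s != 1.0:
        im = ImageEnhance.Sharpness(im).enhance(s)
    return np.asarray(im)


def augment_batch(batch: LabeledImageSet, config: AugmentConfig,
                  epoch_seed: int) -> LabeledImageSet:
    """Independently transform every image; labels and cardinality unchanged.

    Per-image randomness is keyed on ``(config.seed, epoch_seed, index)``,
    so results are reproducible across runs and independent of processing
    order.
    """
    if len(batch) == 0:
        raise ValueError("batch must be non-empty")
    out = np.empty_like(batch.images)
    for i, img in enumerate(batch.images):
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=config.seed, spawn_key=(int(epoch_seed), i)))
        params = sample_params(config, rng)
        img = geometric_transform(img, params)
        if config.photometric_active:
            img = photometric_transform(img, params)
        out[i] = img
    return LabeledImageSet(out, batch.labels.copy(), batch.class_names)


def contact_sheet(images: np.ndarray, n_cols: int = 8) -> np.ndarray:
    """Tile images into one uint8 sheet (for the augment-preview command)."""
    imgs = np.asarray(images)
    n, h, w, _ = imgs.shape
    n_rows = -(-n // n_cols)
    sheet = np.full((n_rows * h, n_cols * w, 3), 255, np.uint8)
    for i, im in enumerate(imgs):
        r, c = divmod(i, n_cols)
        sheet[r * h:(r + 1) * h, c * w:(c + 1) * w] = im
    return sheet
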