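"""Image transforms for training: geometry pipeline plus stochastic augments.

The geometry pipeline differs by class.  LGG training slices are resized to
448x448, center-cropped to 224x224, then randomly cropped to 160x160; the
stochastic augments (flip, cyclic shift, rotation, salt-and-pepper noise) are
applied to LGG training slices only, each enabled transform with probability
0.5.  HGG training slices and *all* validation slices get a deterministic
center crop to 160x160 (zero-padding first when the slice is smaller).

All transforms act on channel-first (C, H, W) arrays and apply the same
geometric map to every channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import ValidationError

TARGET_SIZE = 160
NOMINAL_SLICE_SIZE = 240   # the geometry pipeline is defined on 240x240 slices
RESIZE_SIZE = 448
CENTER_CROP_SIZE = 224


def _pad_to(image: np.ndarray, size: int) -> np.ndarray:
    """Symmetric zero-pad the spatial dims up to at least size x size."""
    _, h, w = image.shape
    if h >= size and w >= size:
        return image
    pad_h, pad_w = max(size - h, 0), max(size - w, 0)
    return np.pad(image, ((0, 0),
                          (pad_h // 2, pad_h - pad_h // 2),
                          (pad_w // 2, pad_w - pad_w // 2)))


@dataclass
class AugmentConfig:
    enable_flip: bool = True
    enable_cyclic_shift: bool = True
    enable_rotation: bool = True
    enable_salt_pepper: bool = True
    enable_duplication: bool = True
    rotation_range_deg: tuple[float, float] = (-180.0, 180.0)
    salt_pepper_fraction: float = 0.02
    shift_max_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.rotation_range_deg
        if not np.isclose(lo, -hi):
            raise ValidationError(f"rotation range must be symmetric, got {self.rotation_range_deg}")
        if not 0.0 <= self.salt_pepper_fraction <= 1.0:
            raise ValidationError("salt_pepper_fraction must lie in [0, 1]")
        if not 0.0 < self.shift_max_fraction <= 1.0:
            raise ValidationError("shift_max_fraction must lie in (0, 1]")

    @classmethod
    def disabled(cls) -> "AugmentConfig":
        return cls(enable_flip=False, enable_cyclic_shift=False,
                   enable_rotation=False, enable_salt_pepper=False,
                   enable_duplication=False)


def _check_chw(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3:
        raise ValidationError(f"expected (C, H, W) image, got shape {image.shape}")
    return image


def crop(image: np.ndarray, size: int, mode: str = "center",
         rng: np.random.Generator | None = None) -> np.ndarray:
    """Center (deterministic, offset floor((H-size)/2)) or random crop."""
    image = _check_chw(image)
    _, h, w = image.shape
    if size > h or size > w:
        raise ValidationError(f"crop size {size} exceeds image extent {(h, w)}")
    if mode == "center":
        top, left = (h - size) // 2, (w - size) // 2
    elif mode == "random":
        if rng is None:
            raise ValidationError("random crop requires an rng")
        top = int(rng.integers(0, h - size + 1))
        left = int(rng.integers(0, w - size + 1))
    else:
        raise ValidationError(f"unknown crop mode {mode!r}")
    return image[:, top:top + size, left:left + size].copy()


def resize(image: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resize of every channel to size x size (Pillow backend)."""
    image = _check_chw(image)
    if size <= 0:
        raise ValidationError("resize target must be positive")
    if image.shape[1] == size and image.shape[2] == size:
        return image.copy()
    out = np.empty((image.shape[0], size, size), dtype=np.float32)
    for ch in range(image.shape[0]):
        pil = Image.fromarray(np.ascontiguousarray(image[ch], dtype=np.float32),
                              mode="F")
        out[ch] = np.asarray(pil.resize((size, size), Image.BILINEAR))
    return out


def flip(image: np.ndarray, axis: str) -> np.ndarray:
    """Mirror about the named axis: horizontal mirrors columns, vertical rows."""
    image = _check_chw(image)
    if axis == "horizontal":
        return image[:, :, ::-1].copy()
    if axis == "vertical":
        return image[:, ::-1, :].copy()
    raise ValidationError(f"axis must be horizontal or vertical, got {axis!r}")


def cyclic_shift(image: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Translate with wrap-around: pixel (r, c) -> ((r+dy) mod H, (c+dx) mod W).

    Conserves the exact multiset of pixel values.
    """
    image = _check_chw(image)
    return np.roll(image, shift=(int(dy), int(dx)), axis=(1, 2))


def random_cyclic_shift(image: np.ndarray, shift_max_fraction: float,
                        rng: np.random.Generator) -> np.ndarray:
    _, h, w = _check_chw(image).shape
    max_dy = max(int(shift_max_fraction * h), 1)
    max_dx = max(int(shift_max_fraction * w), 1)
    dy = int(rng.integers(-max_dy, max_dy + 1))
    dx = int(rng.integers(-max_dx, max_dx + 1))
    return cyclic_shift(image, dx, dy)


def rotate(image: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate about the image center, bilinear, zero fill outside."""
    image = _check_chw(image)
    if not np.isfinite(angle_deg):
        raise ValidationError("rotation angle must be finite")
    if angle_deg % 360 == 0:
        return image.copy()
    out = ndimage.rotate(image.astype(np.float32), angle_deg, axes=(1, 2),
                         reshape=False, order=1, mode="constant", cval=0.0)
    return out.astype(np.float32)


def salt_pepper(image: np.ndarray, fraction: float,
                rng: np.random.Generator) -> np.ndarray:
    """Corrupt round(fraction*H*W) pixel positions, equal odds salt/pepper.

    The same positions (and the same salt/pepper decision) apply to every
    channel; salt sets the channel's maximum value, pepper sets 0.
    """
    image = _check_chw(image)
    if not 0.0 <= fraction <= 1.0:
        raise ValidationError("salt/pepper fraction must lie in [0, 1]")
    c, h, w = image.shape
    n = int(round(fraction * h * w))
    if n == 0:
        return image.copy()
    out = image.copy()
    positions = rng.choice(h * w, size=n, replace=False)
    is_salt = rng.uniform(size=n) < 0.5
    rows, cols = np.unravel_index(positions, (h, w))
    channel_max = out.reshape(c, -1).max(axis=1)
    for ch in range(c):
        out[ch, rows[is_salt], cols[is_salt]] = channel_max[ch]
        out[ch, rows[~is_salt], cols[~is_salt]] = 0.0
    return out


def eval_transform(image: np.ndarray, size: int = TARGET_SIZE) -> np.ndarray:
    """Deterministic center crop to the target size, zero-padding undersized
    slices symmetrically first (padding is logged by the caller's config)."""
    image = _check_chw(image)
    return crop(_pad_to(image, size), size, mode="center")


def lgg_train_transform(image: np.ndarray, config: AugmentConfig,
                        rng: np.random.Generator,
                        size: int = TARGET_SIZE) -> np.ndarray:
    """Full LGG training pipeline.

    Geometry: resize to 448, center-crop 224, random-crop to 160.  Then each
    enabled stochastic augment fires independently with probability 0.5.
    With all toggles off the path is geometry-only (random crop remains).
    Undersized slices are first zero-padded to the nominal 240x240, so the
    magnification relative to the deterministic eval path is the same at
    every grid scale.
    """
    out = resize(_pad_to(image, NOMINAL_SLICE_SIZE), RESIZE_SIZE)
    out = crop(out, CENTER_CROP_SIZE, mode="center")
    out = crop(out, size, mode="random", rng=rng)
    if config.enable_flip and rng.uniform() < 0.5:
        out = flip(out, "horizontal" if rng.uniform() < 0.5 else "vertical")
    if config.enable_cyclic_shift and rng.uniform() < 0.5:
        out = random_cyclic_shift(out, config.shift_max_fraction, rng)
    if config.enable_rotation and rng.uniform() < 0.5:
        out = rotate(out, float(rng.uniform(*config.rotation_range_deg)))
    if config.enable_salt_pepper and rng.uniform() < 0.5:
        out = salt_pepper(out, config.salt_pepper_fraction, rng)
    return out
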