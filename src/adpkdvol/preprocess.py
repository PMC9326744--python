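"""Slice-level preprocessing: normalization, spatial transforms, augmentation.

The training and inference paths are deliberately asymmetric:

* training: aspect-preserving resize of the longer side to
  ``train_map_size`` (default 640), zero-pad to square, then a central
  ``train_crop_size`` (default 512) crop — focusing the model on central
  anatomy;
* inference: a direct, crop-free resize to ``infer_size`` so organs near
  the image border (the liver especially) are never truncated, with an
  exact inverse descriptor to map probabilities back to the native grid.

Intensities and probabilities are resampled bilinearly; label maps use
nearest-neighbour so they stay categorical.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from skimage import transform as sktransform

__all__ = [
    "AugmentConfig",
    "PreprocessConfig",
    "InverseMap",
    "minmax_normalize",
    "train_transform",
    "infer_transform",
    "restore_native",
    "augment",
]


@dataclass
class AugmentConfig:
    """Spatially paired augmentation: affine + flip + intensity jitter."""

    enabled: bool = True
    rotate_deg: float = 10.0
    scale_frac: float = 0.10
    translate_frac: float = 0.05
    hflip_prob: float = 0.5
    brightness: float = 0.10
    contrast: float = 0.10


@dataclass
class PreprocessConfig:
    train_map_size: int = 640
    train_crop_size: int = 512
    infer_size: int = 512
    augment: AugmentConfig = field(default_factory=AugmentConfig)

    def __post_init__(self) -> None:
        if min(self.train_map_size, self.train_crop_size, self.infer_size) <= 0:
            raise ValueError("sizes must be positive")
        if self.train_crop_size > self.train_map_size:
            raise ValueError("train_crop_size must not exceed train_map_size")
        if isinstance(self.augment, dict):
            self.augment = AugmentConfig(**self.augment)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        return cls(**d)


def minmax_normalize(slice2d: np.ndarray) -> np.ndarray:
    """Map the slice minimum to 0.0 and the maximum to 1.0.

    A constant slice maps to all zeros (it carries no contrast and would
    otherwise divide by zero).  Non-finite values raise ``ValueError``.
    """
    x = np.asarray(slice2d, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("slice contains NaN or Inf")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def _resize(arr: np.ndarray, shape: tuple[int, int], order: int) -> np.ndarray:
    if arr.shape == tuple(shape):
        return arr.astype(np.float64, copy=True)
    return sktransform.resize(
        arr.astype(np.float64),
        shape,
        order=order,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )


def _pad_to_square(arr: np.ndarray, size: int) -> np.ndarray:
    h, w = arr.shape
    out = np.zeros((size, size), dtype=arr.dtype)
    top = (size - h) // 2
    left = (size - w) // 2
    out[top : top + h, left : left + w] = arr
    return out


def _center_crop(arr: np.ndarray, size: int) -> np.ndarray:
    h, w = arr.shape
    top = (h - size) // 2
    left = (w - size) // 2
    return arr[top : top + size, left : left + size]


def train_transform(
    slice2d: np.ndarray, label2d: np.ndarray, cfg: PreprocessConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Training-path geometry: map to ``train_map_size``², center-crop.

    The resize preserves aspect ratio (longer side mapped to the target,
    shorter side zero-padded) so anatomy is never anisotropically
    stretched during training.
    """
    img = np.asarray(slice2d, dtype=np.float64)
    lab = np.asarray(label2d)
    if img.shape != lab.shape:
        raise ValueError("slice and label must be congruent")
    h, w = img.shape
    scale = cfg.train_map_size / max(h, w)
    new_shape = (max(1, round(h * scale)), max(1, round(w * scale)))
    img_r = _resize(img, new_shape, order=1)
    lab_r = _resize(lab.astype(np.float64), new_shape, order=0)
    img_sq = _pad_to_square(img_r, cfg.train_map_size)
    lab_sq = _pad_to_square(lab_r, cfg.train_map_size)
    img_c = _center_crop(img_sq, cfg.train_crop_size)
    lab_c = _center_crop(lab_sq, cfg.train_crop_size)
    return img_c, np.round(lab_c).astype(lab.dtype if np.issubdtype(lab.dtype, np.integer) else np.int64)


@dataclass(frozen=True)
class InverseMap:
    """Exact descriptor to undo :func:`infer_transform`."""

    native_shape: tuple[int, int]
    infer_size: int


def infer_transform(slice2d: np.ndarray, cfg: PreprocessConfig) -> tuple[np.ndarray, InverseMap]:
    """Inference-path geometry: direct crop-free resize to ``infer_size``²."""
    img = np.asarray(slice2d, dtype=np.float64)
    out = _resize(img, (cfg.infer_size, cfg.infer_size), order=1)
    return out, InverseMap(native_shape=img.shape, infer_size=cfg.infer_size)


def restore_native(prob_slice: np.ndarray, inverse: InverseMap) -> np.ndarray:
    """Resize a probability slice back to the native in-plane grid."""
    p = np.asarray(prob_slice, dtype=np.float64)
    if p.shape != (inverse.infer_size, inverse.infer_size):
        raise ValueError(
            f"expected a {inverse.infer_size}x{inverse.infer_size} slice, got {p.shape}"
        )
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probability values must lie in [0, 1]")
    out = _resize(p, inverse.native_shape, order=1)
    return np.clip(out, 0.0, 1.0)


def augment(
    slice2d: np.ndarray, label2d: np.ndarray, cfg: PreprocessConfig, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one random augmentation draw identically to image and label.

    Spatial part: rotation within ±``rotate_deg``, isotropic scale within
    ±``scale_frac``, translation within ±``translate_frac`` of the slice
    size, and a horizontal (patient left–right, first in-plane axis) flip.
    Intensity part (image only): brightness shift and contrast scaling,
    clipped back to [0, 1].  Deterministic for a given seed; identity when
    augmentation is disabled.
    """
    img = np.asarray(slice2d, dtype=np.float64)
    lab = np.asarray(label2d)
    if img.shape != lab.shape:
        raise ValueError("slice and label must be congruent")
    a = cfg.augment
    if not a.enabled:
        return img.copy(), lab.copy()

    rng = np.random.default_rng(seed)
    angle = np.deg2rad(rng.uniform(-a.rotate_deg, a.rotate_deg))
    scale = 1.0 + rng.uniform(-a.scale_frac, a.scale_frac)
    ty, tx = rng.uniform(-a.translate_frac, a.translate_frac, size=2) * np.asarray(img.shape)
    do_flip = rng.random() < a.hflip_prob
    brightness = rng.uniform(-a.brightness, a.brightness)
    contrast = 1.0 + rng.uniform(-a.contrast, a.contrast)

    center = (np.asarray(img.shape[::-1]) - 1) / 2.0  # (x, y) order for skimage
    tf = (
        sktransform.AffineTransform(translation=-center)
        + sktransform.AffineTransform(rotation=angle, scale=scale)
        + sktransform.AffineTransform(translation=center + np.array([tx, ty]))
    )
    img_t = sktransform.warp(img, tf.inverse, order=1, mode="constant", cval=0.0, preserve_range=True)
    lab_t = sktransform.warp(
        lab.astype(np.float64), tf.inverse, order=0, mode="constant", cval=0.0, preserve_range=True
    )
    if do_flip:
        img_t = img_t[::-1, :].copy()
        lab_t = lab_t[::-1, :].copy()

    img_t = np.clip((img_t - img_t.mean()) * contrast + img_t.mean() + brightness, 0.0, 1.0)
    lab_out = np.round(lab_t).astype(lab.dtype if np.issubdtype(lab.dtype, np.integer) else np.int64)
    return img_t, lab_out
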