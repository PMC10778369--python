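"""Data augmentation: shared geometric transforms, weak/strong photometric
views, and feature-space perturbation.

The three views of one unlabeled image share a single geometric transform
(scale, crop, flips) so their prediction maps stay pixel-aligned; the two
strong views differ only by independent photometric perturbations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize as sk_resize

from .nn import Tensor, dropout_channels

__all__ = ["AugmentationPolicy", "GeometricParams", "sample_geometry",
           "apply_geometry", "color_jitter", "make_views", "feature_perturb",
           "normalize_image", "dataset_stats"]


@dataclass(frozen=True)
class AugmentationPolicy:
    kind: str = "strong"                  # "weak" | "strong"
    scale_range: tuple[float, float] = (0.5, 1.5)
    crop: int = 256
    flip: bool = True
    jitter_strength: float = 0.5          # 0 disables color jitter
    grayscale_prob: float = 0.2
    blur_prob: float = 0.3

    def __post_init__(self):
        if self.kind not in ("weak", "strong"):
            raise ValueError("kind must be 'weak' or 'strong'")
        if self.kind == "weak":
            # weak policy never jitters color
            object.__setattr__(self, "jitter_strength", 0.0)
            object.__setattr__(self, "grayscale_prob", 0.0)
            object.__setattr__(self, "blur_prob", 0.0)


@dataclass(frozen=True)
class GeometricParams:
    scale: float
    top: int
    left: int
    flip_h: bool
    flip_v: bool
    crop: int


def sample_geometry(shape_hw: tuple[int, int], policy: AugmentationPolicy,
                    rng: np.random.Generator) -> GeometricParams:
    h, w = shape_hw
    crop = policy.crop
    lo, hi = policy.scale_range
    # keep the scaled image at least crop-sized
    min_scale = max(lo, crop / h, crop / w)
    scale = float(rng.uniform(min_scale, max(hi, min_scale)))
    sh, sw = int(round(h * scale)), int(round(w * scale))
    sh, sw = max(sh, crop), max(sw, crop)
    top = int(rng.integers(0, sh - crop + 1))
    left = int(rng.integers(0, sw - crop + 1))
    flip_h = policy.flip and bool(rng.random() < 0.5)
    flip_v = policy.flip and bool(rng.random() < 0.5)
    return GeometricParams(scale, top, left, flip_h, flip_v, crop)


def apply_geometry(image: np.ndarray, params: GeometricParams,
                   is_mask: bool = False) -> np.ndarray:
    """Apply scale/crop/flips; nearest-neighbor for label maps."""
    h, w = image.shape[:2]
    if h < params.crop or w < params.crop:
        raise ValueError("image smaller than crop size")
    sh = max(int(round(h * params.scale)), params.crop)
    sw = max(int(round(w * params.scale)), params.crop)
    if (sh, sw) != (h, w):
        if is_mask:
            out = sk_resize(image, (sh, sw), order=0, preserve_range=True,
                            anti_aliasing=False).astype(image.dtype)
        else:
            out = sk_resize(image.astype(np.float64), (sh, sw), order=1,
                            preserve_range=True, anti_aliasing=params.scale < 1.0)
    else:
        out = image.astype(np.float64) if not is_mask else image
    out = out[params.top:params.top + params.crop,
              params.left:params.left + params.crop]
    if params.flip_h:
        out = out[:, ::-1]
    if params.flip_v:
        out = out[::-1, :]
    return np.ascontiguousarray(out)


def color_jitter(image: np.ndarray, strength: float, rng: np.random.Generator,
                 grayscale_prob: float = 0.0, blur_prob: float = 0.0) -> np.ndarray:
    """Photometric perturbation of a float RGB image in [0, 255]."""
    img = image.astype(np.float64)
    if strength > 0:
        brightness = 1.0 + strength * rng.uniform(-0.3, 0.3)
        contrast = 1.0 + strength * rng.uniform(-0.4, 0.4)
        gains = 1.0 + strength * rng.uniform(-0.15, 0.15, size=3)
        img = img * brightness * gains
        img = (img - img.mean()) * contrast + img.mean()
        if rng.random() < grayscale_prob:
            gray = img @ np.array([0.299, 0.587, 0.114])
            mix = rng.uniform(0.4, 1.0)
            img = (1 - mix) * img + mix * gray[..., None]
        if rng.random() < blur_prob:
            img = ndimage.gaussian_filter(img, (rng.uniform(0.3, 1.0),) * 2 + (0,))
    return np.clip(img, 0, 255)


def make_views(image: np.ndarray, policy: AugmentationPolicy,
               seed: int | np.random.Generator):
    """Produce (xw, xs1, xs2): one shared geometric transform, weak
    photometrics for xw, two independent strong photometrics."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    geom = sample_geometry(image.shape[:2], policy, rng)
    base = apply_geometry(image, geom)
    xw = base
    xs1 = color_jitter(base, policy.jitter_strength, rng,
                       policy.grayscale_prob, policy.blur_prob)
    xs2 = color_jitter(base, policy.jitter_strength, rng,
                       policy.grayscale_prob, policy.blur_prob)
    return xw, xs1, xs2


def feature_perturb(features: Tensor, drop_rate: float,
                    seed: int | np.random.Generator) -> Tensor:
    """Channel dropout with 1/(1-rate) rescaling; identity at rate 0."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return dropout_channels(features, drop_rate, rng)


def dataset_stats(images: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean/std over a list of uint8 RGB images (for the
    color-normalization step)."""
    acc = np.concatenate([im.reshape(-1, 3).astype(np.float64) / 255.0
                          for im in images])
    return acc.mean(axis=0), acc.std(axis=0) + 1e-6


def normalize_image(image: np.ndarray, mean: np.ndarray, std: np.ndarray) -> np.ndarray:
    """uint8/float HWC RGB -> normalized CHW float array."""
    img = np.asarray(image, dtype=np.float64) / 255.0
    img = (img - mean) / std
    return np.ascontiguousarray(img.transpose(2, 0, 1))
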