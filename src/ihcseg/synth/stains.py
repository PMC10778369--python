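"""Forward stain model: compose hematoxylin/DAB concentration maps in
optical-density space and convert to 8-bit RGB.

The same basis vectors are used by the quantification module's color
deconvolution, so synthesis → unmixing round-trips are exact up to
8-bit quantization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Ruifrok–Johnston H-DAB absorption vectors (rows, unit norm).
HEMATOXYLIN_RGB = np.array([0.650, 0.704, 0.286])
DAB_RGB = np.array([0.268, 0.570, 0.776])


def _residual(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    r = np.cross(v1, v2)
    return r / np.linalg.norm(r)


@dataclass(frozen=True)
class StainVectors:
    """Unit optical-density RGB absorption vectors for a two-stain model."""

    hematoxylin: np.ndarray = field(default_factory=lambda: HEMATOXYLIN_RGB.copy())
    dab: np.ndarray = field(default_factory=lambda: DAB_RGB.copy())

    def __post_init__(self):
        for name in ("hematoxylin", "dab"):
            v = np.asarray(getattr(self, name), dtype=np.float64)
            n = np.linalg.norm(v)
            if n == 0:
                raise ValueError(f"{name} vector is zero")
            object.__setattr__(self, name, v / n)
        if np.linalg.matrix_rank(self.matrix()) < 3:
            raise ValueError("stain vectors are linearly dependent")

    @property
    def residual(self) -> np.ndarray:
        return _residual(self.hematoxylin, self.dab)

    def matrix(self) -> np.ndarray:
        """3x3 matrix with stain vectors as rows (H, DAB, residual)."""
        return np.stack([self.hematoxylin, self.dab, self.residual])


DEFAULT_STAINS = StainVectors()


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Convert a HxWx3 optical-density image to 8-bit RGB.

    Inverse of ``rgb_to_od``: I = 256 * 10^(-OD) - 1.
    """
    intensity = 256.0 * np.power(10.0, -np.asarray(od, dtype=np.float64)) - 1.0
    return np.clip(np.round(intensity), 0, 255).astype(np.uint8)


def rgb_to_od(rgb: np.ndarray) -> np.ndarray:
    """OD = -log10((I + 1) / 256), elementwise per channel."""
    return -np.log10((np.asarray(rgb, dtype=np.float64) + 1.0) / 256.0)


def render_rgb(c_hema: np.ndarray, c_dab: np.ndarray,
               vectors: StainVectors = DEFAULT_STAINS) -> np.ndarray:
    """Render per-pixel stain concentrations into an RGB image."""
    od = (c_hema[..., None] * vectors.hematoxylin
          + c_dab[..., None] * vectors.dab)
    return od_to_rgb(od)
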