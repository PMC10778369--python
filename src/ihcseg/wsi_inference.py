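"""Whole-slide inference: context-window tiling, tissue masking, and
stitching of fused predictions into one stride-8 label mask.

Coordinates are 0-based, row-major, with half-open rectangles
[r0, r1) x [c0, c1).  Cores partition the image exactly on an S/2 grid;
each core's context extends S/4 beyond it per side and is reflect-padded
where it leaves the image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .multiscale import (AFFCascade, MultiScaleGeometry, branch_outputs,
                         fuse_triplet)
from .nn import no_grad

__all__ = ["WSIWindow", "LabelMask", "tissue_mask", "tile_plan", "infer_wsi",
           "infer_tiles_nocontext", "seam_disagreement", "OUT_STRIDE"]

OUT_STRIDE = 8


@dataclass(frozen=True)
class WSIWindow:
    core: tuple[int, int, int, int]      # r0, r1, c0, c1 within the image
    context: tuple[int, int, int, int]   # may extend outside the image
    pad: tuple[int, int, int, int]       # reflect pad: top, bottom, left, right


@dataclass
class LabelMask:
    """Class-index map at OUT_STRIDE relative to level-0 pixels."""

    data: np.ndarray
    stride: int = OUT_STRIDE
    provenance: dict = field(default_factory=dict)

    def to_level0(self, shape_hw: tuple[int, int]) -> np.ndarray:
        """Nearest-neighbor upsample back to level-0 pixel dimensions."""
        h, w = shape_hw
        ys = np.minimum(np.arange(h) // self.stride, self.data.shape[0] - 1)
        xs = np.minimum(np.arange(w) // self.stride, self.data.shape[1] - 1)
        return self.data[np.ix_(ys, xs)]


def tissue_mask(lowres_rgb: np.ndarray, sat_threshold: float = 0.05) -> np.ndarray:
    """Tissue = saturation above threshold after 5x5 median smoothing."""
    rgb = np.asarray(lowres_rgb, dtype=np.float64) / 255.0
    mx, mn = rgb.max(axis=-1), rgb.min(axis=-1)
    sat = np.where(mx > 0, (mx - mn) / np.maximum(mx, 1e-9), 0.0)
    sat = ndimage.median_filter(sat, size=5)
    return sat > sat_threshold


def tile_plan(image_dims: tuple[int, int], geom: MultiScaleGeometry) -> list[WSIWindow]:
    h, w = image_dims
    if h < 1 or w < 1:
        raise ValueError("image dimensions must be positive")
    half, quarter = geom.crop_side, geom.context_side // 4
    windows = []
    for r0 in range(0, h, half):
        for c0 in range(0, w, half):
            r1, c1 = min(r0 + half, h), min(c0 + half, w)
            ctx = (r0 - quarter, r0 - quarter + geom.context_side,
                   c0 - quarter, c0 - quarter + geom.context_side)
            pad = (max(0, -ctx[0]), max(0, ctx[1] - h),
                   max(0, -ctx[2]), max(0, ctx[3] - w))
            windows.append(WSIWindow((r0, r1, c0, c1), ctx, pad))
    return windows


def _extract_context(image: np.ndarray, win: WSIWindow) -> np.ndarray:
    r0, r1, c0, c1 = win.context
    h, w = image.shape[:2]
    patch = image[max(0, r0):min(h, r1), max(0, c0):min(w, c1)]
    pt, pb, pl, pr = win.pad
    if any((pt, pb, pl, pr)):
        width = ((pt, pb), (pl, pr)) + ((0, 0),) * (image.ndim - 2)
        patch = np.pad(patch, width, mode="reflect")
    return patch


def infer_wsi(forward_fn, cascade: AFFCascade, image: np.ndarray,
              geom: MultiScaleGeometry, sat_threshold: float = 0.05,
              skip_background: bool = True,
              provenance: dict | None = None) -> LabelMask:
    """Stitched stride-8 class mask for a whole-slide-like RGB image.

    Windows whose core contains no tissue are skipped (left background).
    Disjoint core writes make the result independent of visit order.
    """
    h, w = image.shape[:2]
    out = np.zeros((-(-h // OUT_STRIDE), -(-w // OUT_STRIDE)), dtype=np.uint8)
    tissue = tissue_mask(image, sat_threshold) if skip_background else None
    cascade.eval()
    for win in tile_plan((h, w), geom):
        r0, r1, c0, c1 = win.core
        if tissue is not None and not tissue[r0:r1, c0:c1].any():
            continue
        context = _extract_context(image, win)
        with no_grad():
            triplet = branch_outputs(forward_fn, context, geom)
            fused = fuse_triplet(triplet, cascade).data[0]
        labels = np.argmax(fused, axis=0).astype(np.uint8)
        gr0, gc0 = r0 // OUT_STRIDE, c0 // OUT_STRIDE
        gr1, gc1 = -(-r1 // OUT_STRIDE), -(-c1 // OUT_STRIDE)
        out[gr0:gr1, gc0:gc1] = labels[:gr1 - gr0, :gc1 - gc0]
    return LabelMask(out, OUT_STRIDE, provenance or {})


def infer_tiles_nocontext(forward_fn, image: np.ndarray,
                          geom: MultiScaleGeometry) -> LabelMask:
    """Baseline: independent S/2 tiles, no surrounding context, no fusion."""
    h, w = image.shape[:2]
    half = geom.crop_side
    out = np.zeros((-(-h // OUT_STRIDE), -(-w // OUT_STRIDE)), dtype=np.uint8)
    for r0 in range(0, h, half):
        for c0 in range(0, w, half):
            r1, c1 = min(r0 + half, h), min(c0 + half, w)
            tile = image[r0:r1, c0:c1]
            pr, pc = half - tile.shape[0], half - tile.shape[1]
            if pr or pc:
                tile = np.pad(tile, ((0, pr), (0, pc), (0, 0)), mode="reflect")
            with no_grad():
                scores = np.asarray(forward_fn(tile))
            labels = np.argmax(scores, axis=0).astype(np.uint8)
            gr0, gc0 = r0 // OUT_STRIDE, c0 // OUT_STRIDE
            gr1, gc1 = -(-r1 // OUT_STRIDE), -(-c1 // OUT_STRIDE)
            out[gr0:gr1, gc0:gc1] = labels[:gr1 - gr0, :gc1 - gc0]
    return LabelMask(out, OUT_STRIDE, {})


def seam_disagreement(mask: LabelMask, geom: MultiScaleGeometry,
                      uniform_regions: np.ndarray | None = None) -> float:
    """Fraction of adjacent cross-border pixel pairs (at the mask's stride)
    with different labels, along core borders.  ``uniform_regions`` (bool,
    level-0) restricts the count to pairs whose level-0 ground truth is
    locally uniform."""
    data = mask.data
    gh, gw = data.shape
    step = geom.crop_side // mask.stride
    diff = 0
    total = 0
    for r in range(step, gh, step):
        a, b = data[r - 1, :], data[r, :]
        keep = np.ones(gw, dtype=bool)
        if uniform_regions is not None:
            keep = (uniform_regions[(r - 1) * mask.stride, ::mask.stride][:gw]
                    & uniform_regions[min(r * mask.stride,
                                          uniform_regions.shape[0] - 1), ::mask.stride][:gw])
        diff += int((a[keep] != b[keep]).sum())
        total += int(keep.sum())
    for c in range(step, gw, step):
        a, b = data[:, c - 1], data[:, c]
        keep = np.ones(gh, dtype=bool)
        if uniform_regions is not None:
            keep = (uniform_regions[::mask.stride, (c - 1) * mask.stride][:gh]
                    & uniform_regions[::mask.stride, min(c * mask.stride,
                                                         uniform_regions.shape[1] - 1)][:gh])
        diff += int((a[keep] != b[keep]).sum())
        total += int(keep.sum())
    return diff / total if total else 0.0
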