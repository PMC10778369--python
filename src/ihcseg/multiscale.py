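"""Multi-scale context fusion: corner/center/downscale branch geometry and
the two-level attentional fusion cascade, trained with the backbone frozen.

A context window of side S yields three stride-8 score maps for its
central S/2 crop: p1 from reassembled corner crops (finest), p2 from the
direct center crop, p3 from the 2x-downscaled full window (broadest).
They are blended by two gated fusion modules: p = AFF(AFF(p1, p2), p3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as sk_resize

from .nn import SGD, Conv2d, Module, Tensor, no_grad, resize_bilinear
from .losses import weighted_ce

__all__ = ["MultiScaleGeometry", "BranchTriplet", "AFF", "AFFCascade",
           "plan_geometry", "branch_outputs", "aff_fuse", "fuse_triplet",
           "Stage2Config", "train_stage2", "downsample_mask_nearest",
           "save_cascade", "load_cascade"]

OUT_STRIDE = 8


@dataclass(frozen=True)
class MultiScaleGeometry:
    context_side: int

    def __post_init__(self):
        if self.context_side % 16:
            raise ValueError("context side must be divisible by 16")

    @property
    def crop_side(self) -> int:
        return self.context_side // 2

    @property
    def out_side(self) -> int:
        return self.crop_side // OUT_STRIDE

    @property
    def corner_offsets(self) -> tuple[tuple[int, int], ...]:
        s = self.crop_side
        return ((0, 0), (0, s), (s, 0), (s, s))

    @property
    def center_offset(self) -> tuple[int, int]:
        q = self.context_side // 4
        return (q, q)


def plan_geometry(context_side: int) -> MultiScaleGeometry:
    return MultiScaleGeometry(context_side)


@dataclass
class BranchTriplet:
    p1: Tensor  # corner mosaic, center-cropped
    p2: Tensor  # direct center-crop output
    p3: Tensor  # downscale output, center-cropped and 2x upsampled

    def __post_init__(self):
        if not (self.p1.shape == self.p2.shape == self.p3.shape):
            raise ValueError("branch maps must share shape")


def reassemble_corners(corners: list[np.ndarray], geom: MultiScaleGeometry) -> np.ndarray:
    """Place the four corner-crop outputs at their stride-8 offsets; exact
    tiling, no overlap."""
    o = geom.out_side
    c = corners[0].shape[-3]
    mosaic = np.empty(corners[0].shape[:-3] + (c, 2 * o, 2 * o),
                      dtype=corners[0].dtype)
    for (dy, dx), cm in zip(geom.corner_offsets, corners):
        r, col = dy // OUT_STRIDE, dx // OUT_STRIDE
        mosaic[..., :, r:r + o, col:col + o] = cm
    return mosaic


def branch_outputs(forward_fn, context_image: np.ndarray,
                   geom: MultiScaleGeometry) -> BranchTriplet:
    """Run the frozen backbone over the three views of one context window.

    ``forward_fn(rgb HxWx3) -> (C, H/8, W/8) ndarray`` encapsulates the
    network plus its input normalization; it is never trained here.
    """
    s, half, o = geom.context_side, geom.crop_side, geom.out_side
    if context_image.shape[:2] != (s, s):
        raise ValueError(f"context image must be {s}x{s}")
    corners = [np.asarray(forward_fn(context_image[dy:dy + half, dx:dx + half]))
               for dy, dx in geom.corner_offsets]
    mosaic = reassemble_corners(corners, geom)
    q = o // 2
    p1 = mosaic[..., q:q + o, q:q + o]

    cy, cx = geom.center_offset
    p2 = np.asarray(forward_fn(context_image[cy:cy + half, cx:cx + half]))

    small = sk_resize(context_image.astype(np.float64), (half, half), order=1,
                      preserve_range=True, anti_aliasing=True)
    p3_full = np.asarray(forward_fn(small))
    p3_center = p3_full[..., o // 4:o // 4 + q, o // 4:o // 4 + q]
    p3 = resize_bilinear(Tensor(p3_center), (o, o)).data
    return BranchTriplet(p1=Tensor(p1), p2=Tensor(p2), p3=Tensor(p3))


class AFF(Module):
    """Gated fusion of two equally shaped score maps.

    The gate is a sigmoid over the sum of a local (per-pixel) and a global
    (pooled) two-layer channel-attention context computed on a + b:
    fused = g * a + (1 - g) * b.
    """

    def __init__(self, channels: int, reduction: int = 4,
                 rng: np.random.Generator | None = None):
        super().__init__()
        hidden = max(1, channels // reduction)
        self.local1 = Conv2d(channels, hidden, 1, rng=rng)
        self.local2 = Conv2d(hidden, channels, 1, rng=rng)
        self.global1 = Conv2d(channels, hidden, 1, rng=rng)
        self.global2 = Conv2d(hidden, channels, 1, rng=rng)
        self._forced_gate: float | None = None  # test hook

    def gate(self, a: Tensor, b: Tensor) -> Tensor:
        u = a + b
        local = self.local2(self.local1(u).relu())
        pooled = u.mean(axis=(-2, -1), keepdims=True)
        glob = self.global2(self.global1(pooled).relu())
        return (local + glob).sigmoid()

    def forward(self, a, b) -> Tensor:
        a = a if isinstance(a, Tensor) else Tensor(a)
        b = b if isinstance(b, Tensor) else Tensor(b)
        if a.ndim == 3:
            a = a.reshape((1,) + a.shape)
        if b.ndim == 3:
            b = b.reshape((1,) + b.shape)
        if a.shape != b.shape:
            raise ValueError("AFF inputs must share shape")
        g = (Tensor(np.full(a.shape, self._forced_gate))
             if self._forced_gate is not None else self.gate(a, b))
        return g * a + (1.0 - g) * b


def aff_fuse(a, b, aff: AFF) -> Tensor:
    return aff(a, b)


class AFFCascade(Module):
    """The two fusion modules applied finest-first:
    p = AFF2(AFF1(p1, p2), p3)."""

    def __init__(self, channels: int = 3, reduction: int = 4, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.aff1 = AFF(channels, reduction, rng)
        self.aff2 = AFF(channels, reduction, rng)

    def forward(self, triplet: BranchTriplet) -> Tensor:
        return self.aff2(self.aff1(triplet.p1, triplet.p2), triplet.p3)


def fuse_triplet(triplet: BranchTriplet, cascade: AFFCascade) -> Tensor:
    return cascade(triplet)


def downsample_mask_nearest(mask: np.ndarray, out_side: int) -> np.ndarray:
    """Nearest-neighbor downsample of a class mask to out_side x out_side."""
    h, w = mask.shape
    ys = (np.arange(out_side) * (h / out_side)).astype(int)
    xs = (np.arange(out_side) * (w / out_side)).astype(int)
    return mask[np.ix_(ys, xs)]


def save_cascade(cascade: AFFCascade, path: str) -> None:
    import os
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    np.savez(path, **cascade.state_dict())


def load_cascade(path: str, channels: int = 3, seed: int = 0) -> AFFCascade:
    cascade = AFFCascade(channels=channels, seed=seed)
    data = np.load(path if path.endswith(".npz") else path + ".npz")
    cascade.load_state_dict({k: data[k] for k in data.files})
    return cascade


@dataclass
class Stage2Config:
    lr: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 0.0005
    epochs: int = 5
    seed: int = 0
    reduction: int = 4


def train_stage2(forward_fn, dataset, geom: MultiScaleGeometry,
                 cfg: Stage2Config, class_weights=None,
                 log=None) -> AFFCascade:
    """Fit the fusion cascade on (context image, center ground truth) pairs.

    Only cascade parameters are updated; the backbone behind ``forward_fn``
    is invoked under ``no_grad`` and cannot change.  Ground truth is the
    center-crop class mask nearest-downsampled to the output side.
    """
    cascade = AFFCascade(seed=cfg.seed)
    opt = SGD(cascade.parameters(), cfg.lr, cfg.momentum, cfg.weight_decay)
    if cfg.epochs == 0:
        return cascade
    half = geom.crop_side
    triplets, gts = [], []
    for context, center_gt in dataset:
        if center_gt.shape != (half, half):
            raise ValueError("ground truth must cover the central crop")
        with no_grad():
            triplets.append(branch_outputs(forward_fn, context, geom))
        gts.append(downsample_mask_nearest(center_gt, geom.out_side))
    rng = np.random.default_rng(cfg.seed)
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(triplets))
        ep_loss = 0.0
        for i in order:
            p = cascade(triplets[i]).log_softmax(1).exp()
            loss = weighted_ce(p, gts[i][None], class_weights)
            if not np.isfinite(loss.item()):
                raise FloatingPointError("non-finite fusion loss")
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += loss.item() / len(triplets)
        if log:
            log({"epoch": epoch + 1, "ce": ep_loss})
    return cascade
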