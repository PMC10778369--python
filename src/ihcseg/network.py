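"""Three-branch fully convolutional segmentation network.

The architecture follows the familiar detail/context/boundary split:

* a detail branch that keeps a high-resolution (stride-8) feature map,
* a deeper context branch that aggregates local and global context at
  strides 16/32 plus a pooled global descriptor,
* a shallow boundary branch whose sigmoid output gates the fusion of the
  detail and context features.

All score maps come out at stride 8 and are bilinearly upsampled for the
losses.  The network factors as ``head(extract_features(x))`` so that
feature-space perturbations can be injected between the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (ConvBNReLU, Conv2d, Module, Sequential, Tensor,
                 resize_bilinear)

__all__ = ["NetworkConfig", "NetworkOutputs", "SegNetwork", "build_network",
           "upsample_scores", "OUT_STRIDE"]

OUT_STRIDE = 8

# (stem channels, detail/boundary/context widths, branch depths P/I/D)
_PRESETS = {
    "tiny": dict(stem=(12, 24), shared=32, p_ch=32, i_ch=48, d_ch=16,
                 depths=(2, 3, 1)),
    "S": dict(stem=(24, 48), shared=64, p_ch=64, i_ch=96, d_ch=32,
              depths=(2, 3, 1)),
    "M": dict(stem=(32, 64), shared=96, p_ch=96, i_ch=128, d_ch=48,
              depths=(3, 5, 2)),
    "L": dict(stem=(48, 96), shared=128, p_ch=128, i_ch=192, d_ch=64,
              depths=(4, 6, 3)),
}


@dataclass(frozen=True)
class NetworkConfig:
    num_classes: int = 3
    size_preset: str = "tiny"
    width: float = 1.0
    depths: tuple[int, int, int] | None = None  # (P, I, D); preset default if None

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.size_preset not in _PRESETS:
            raise ValueError(f"unknown preset {self.size_preset!r}")
        depths = self.depths or _PRESETS[self.size_preset]["depths"]
        p, i, d = depths
        if not (i >= p >= d >= 1):
            raise ValueError("branch depths must satisfy deep I >= medium P "
                             ">= shallow D >= 1")
        object.__setattr__(self, "depths", (p, i, d))

    def resolved(self) -> dict:
        cfg = dict(_PRESETS[self.size_preset])
        w = self.width
        for key in ("shared", "p_ch", "i_ch", "d_ch"):
            cfg[key] = max(4, int(round(cfg[key] * w)))
        cfg["stem"] = tuple(max(4, int(round(c * w))) for c in cfg["stem"])
        cfg["depths"] = self.depths
        return cfg


@dataclass
class NetworkOutputs:
    """Stride-8 score maps: auxiliary detail head, fused main head,
    boundary head (logits; apply sigmoid for probabilities)."""

    pls: Tensor
    pl: Tensor
    plb: Tensor

    @property
    def spatial(self) -> tuple[int, int]:
        return self.pl.shape[-2:]


class _GlobalContext(Module):
    """Adds a pooled, 1x1-projected global descriptor back onto the map."""

    def __init__(self, ch: int, rng):
        super().__init__()
        self.proj = Conv2d(ch, ch, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        g = x.mean(axis=(2, 3), keepdims=True)
        return x + self.proj(g)


class SegNetwork(Module):
    def __init__(self, config: NetworkConfig, seed: int = 0):
        super().__init__()
        self.config = config
        cfg = config.resolved()
        rng = np.random.default_rng(seed)
        s0, s1 = cfg["stem"]
        dp, di, dd = cfg["depths"]
        self.stem = Sequential(ConvBNReLU(3, s0, 3, 2, rng=rng),
                               ConvBNReLU(s0, s1, 3, 2, rng=rng))
        self.down8 = ConvBNReLU(s1, cfg["shared"], 3, 2, rng=rng)

        # detail (P) branch: medium depth, keeps stride 8
        self.p_branch = Sequential(*[ConvBNReLU(cfg["shared"] if k == 0 else cfg["p_ch"],
                                                cfg["p_ch"], 3, rng=rng)
                                     for k in range(dp)])
        # context (I) branch: deep, strides 16/32 plus global pooling
        i_layers: list[Module] = [ConvBNReLU(cfg["shared"], cfg["i_ch"], 3, 2, rng=rng)]
        for k in range(1, di - 1):
            stride = 2 if k == 1 else 1
            i_layers.append(ConvBNReLU(cfg["i_ch"], cfg["i_ch"], 3, stride, rng=rng))
        i_layers.append(_GlobalContext(cfg["i_ch"], rng))
        i_layers.append(ConvBNReLU(cfg["i_ch"], cfg["p_ch"], 3, rng=rng))
        self.i_branch = Sequential(*i_layers)
        # boundary (D) branch: shallow, stride 8
        self.d_branch = Sequential(*[ConvBNReLU(cfg["shared"] if k == 0 else cfg["d_ch"],
                                                cfg["d_ch"], 3, rng=rng)
                                     for k in range(dd)])

        self.aux_head = Conv2d(cfg["p_ch"], config.num_classes, 1, rng=rng)
        self.boundary_head = Conv2d(cfg["d_ch"], 1, 1, rng=rng)
        self.fuse = ConvBNReLU(cfg["p_ch"], cfg["p_ch"], 3, rng=rng)
        self.head_conv = Conv2d(cfg["p_ch"], config.num_classes, 1, rng=rng)

    # g: image -> (fused features, auxiliary + boundary logits)
    def extract_features(self, x, boundary_gate_scale: float = 1.0):
        x = x if isinstance(x, Tensor) else Tensor(x)
        h, w = x.shape[-2:]
        if h % OUT_STRIDE or w % OUT_STRIDE:
            raise ValueError(f"input spatial dims must be divisible by {OUT_STRIDE}")
        shared = self.down8(self.stem(x))
        p_feat = self.p_branch(shared)
        i_feat = resize_bilinear(self.i_branch(shared), p_feat.shape[-2:])
        d_feat = self.d_branch(shared)
        plb = self.boundary_head(d_feat)
        pls = self.aux_head(p_feat)
        # boundary attention: detail features dominate where the boundary
        # head fires, context features elsewhere
        alpha = (plb * boundary_gate_scale).sigmoid()
        fused = self.fuse(alpha * p_feat + (1.0 - alpha) * i_feat)
        return fused, pls, plb

    # h: fused features -> main logits
    def head(self, features: Tensor) -> Tensor:
        return self.head_conv(features)

    def forward(self, x) -> NetworkOutputs:
        fused, pls, plb = self.extract_features(x)
        return NetworkOutputs(pls=pls, pl=self.head(fused), plb=plb)

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def build_network(config: NetworkConfig, seed: int = 0) -> SegNetwork:
    return SegNetwork(config, seed=seed)


def upsample_scores(outputs: NetworkOutputs, target_hw: tuple[int, int]) -> NetworkOutputs:
    """Bilinearly upsample all three heads to ``target_hw`` (must be the
    stride-8 multiple of the score-map size)."""
    th, tw = target_hw
    sh, sw = outputs.spatial
    if (th, tw) != (sh * OUT_STRIDE, sw * OUT_STRIDE):
        raise ValueError(f"target {target_hw} is not {OUT_STRIDE}x the "
                         f"score-map size {(sh, sw)}")
    return NetworkOutputs(pls=resize_bilinear(outputs.pls, target_hw),
                          pl=resize_bilinear(outputs.pl, target_hw),
                          plb=resize_bilinear(outputs.plb, target_hw))
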