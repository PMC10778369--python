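"""Training stage 1: joint supervised + consistency optimization.

Each step combines the supervised objective on a labeled batch with the
confidence-gated consistency loss on an unlabeled batch (three forward
flows: weak view, two strong views, and a feature-perturbed weak view).
The pseudo-label forward runs under ``no_grad`` so no gradient ever
reaches it.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict, field

import numpy as np

from .augment import (AugmentationPolicy, apply_geometry, color_jitter,
                      feature_perturb, make_views, normalize_image,
                      dataset_stats, sample_geometry)
from .evaluation import iou_per_class, pooled_iou
from .losses import LossWeights, supervised_loss, unimatch_loss
from .network import NetworkConfig, SegNetwork, build_network, upsample_scores
from .nn import SGD, Tensor, no_grad
from .synth.tiles import LabeledTile, derive_boundary_gt

__all__ = ["Stage1Config", "stage1_step", "train_stage1", "predict_tile",
           "save_checkpoint", "load_checkpoint", "inverse_frequency_weights",
           "make_forward_fn"]


@dataclass
class Stage1Config:
    lr: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 0.0005
    epochs: int = 20
    batch_labeled: int = 4
    batch_unlabeled: int = 4
    crop: int = 128
    drop_rate: float = 0.5
    poly_power: float = 0.9
    seed: int = 0
    checkpoint_dir: str = "checkpoints"
    checkpoint_every: int = 5
    jitter_strength: float = 0.5
    scale_range: tuple[float, float] = (0.5, 1.5)
    network: NetworkConfig = field(default_factory=NetworkConfig)

    def __post_init__(self):
        if self.epochs < 1 or self.lr <= 0 or self.batch_labeled < 1:
            raise ValueError("invalid training configuration")


def inverse_frequency_weights(masks: list[np.ndarray], num_classes: int = 3,
                              clip: float = 10.0) -> tuple[float, ...]:
    counts = np.zeros(num_classes)
    for m in masks:
        counts += np.bincount(np.asarray(m).ravel(), minlength=num_classes)[:num_classes]
    counts = np.maximum(counts, 1.0)
    w = counts.sum() / (num_classes * counts)
    w = np.clip(w / w.min(), 1.0, clip)
    return tuple(float(v) for v in w)


# ------------------------------------------------------------------ batching
def _labeled_batch(tiles: list[LabeledTile], idx: np.ndarray, crop: int,
                   scale_range, mean, std, rng: np.random.Generator):
    imgs, masks, bnds = [], [], []
    policy = AugmentationPolicy(kind="weak", crop=crop, scale_range=scale_range)
    for i in idx:
        t = tiles[i]
        geom = sample_geometry(t.image.shape[:2], policy, rng)
        img = apply_geometry(t.image, geom)
        mask = apply_geometry(t.mask, geom, is_mask=True)
        imgs.append(normalize_image(img, mean, std))
        masks.append(mask)
        bnds.append(derive_boundary_gt(mask))
    return np.stack(imgs), np.stack(masks), np.stack(bnds)


def stage1_step(net: SegNetwork, labeled, unlabeled_images, weights: LossWeights,
                cfg: Stage1Config, opt: SGD, mean, std,
                rng: np.random.Generator) -> dict[str, float]:
    """One SGD update on a labeled batch plus (optionally) an unlabeled batch.

    ``labeled`` is (images NCHW, masks, boundaries); ``unlabeled_images``
    is a list of raw RGB tiles (may be empty).
    """
    if not net.training:
        raise ValueError("network must be in training mode")
    imgs, masks, bnds = labeled
    if len(imgs) == 0:
        raise ValueError("empty labeled batch")
    outputs = net(imgs)
    up = upsample_scores(outputs, imgs.shape[-2:])
    ls, comps = supervised_loss(up, masks, bnds, weights)

    report = {"Ls": ls.item(), **comps, "Lu": 0.0}
    total = ls
    # weight 0 disables the whole unlabeled flow, so such a run is
    # bit-identical to a labeled-only run
    if unlabeled_images and weights.unlabeled_weight > 0:
        policy = AugmentationPolicy(kind="strong", crop=cfg.crop,
                                    scale_range=cfg.scale_range,
                                    jitter_strength=cfg.jitter_strength)
        xw_l, xs1_l, xs2_l = [], [], []
        for im in unlabeled_images:
            xw, xs1, xs2 = make_views(im, policy, rng)
            xw_l.append(normalize_image(xw, mean, std))
            xs1_l.append(normalize_image(xs1, mean, std))
            xs2_l.append(normalize_image(xs2, mean, std))
        xw_b, xs1_b, xs2_b = map(np.stack, (xw_l, xs1_l, xs2_l))

        with no_grad():
            pw = net(xw_b).pl.log_softmax(1).exp().data
        feats, _, _ = net.extract_features(xw_b)
        pfp = net.head(feature_perturb(feats, cfg.drop_rate, rng)).log_softmax(1).exp()
        ps1 = net(xs1_b).pl.log_softmax(1).exp()
        ps2 = net(xs2_b).pl.log_softmax(1).exp()
        lu = unimatch_loss(pw, pfp, ps1, ps2, weights)
        report["Lu"] = lu.item()
        total = total + weights.unlabeled_weight * lu

    if not np.isfinite(total.item()):
        raise FloatingPointError(f"non-finite loss: {report}")
    opt.zero_grad()
    total.backward()
    opt.step()
    report["total"] = total.item()
    return report


# -------------------------------------------------------------- checkpointing
def save_checkpoint(path: str, net: SegNetwork, cfg: Stage1Config, epoch: int,
                    mean, std, opt: SGD | None = None, extra: dict | None = None) -> None:
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    arrays = {k: v for k, v in net.state_dict().items()}
    arrays["__norm_mean"] = np.asarray(mean)
    arrays["__norm_std"] = np.asarray(std)
    if opt is not None:
        for i, v in enumerate(opt.velocity):
            arrays[f"__vel_{i}"] = v
    np.savez(path, **arrays)
    sidecar = {
        "epoch": epoch,
        "seed": cfg.seed,
        "config": _jsonable(asdict(cfg)),
        "network": _jsonable(asdict(cfg.network)),
        "param_hash": net.param_hash(),
    }
    if extra:
        sidecar.update(_jsonable(extra))
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def load_checkpoint(path: str):
    """Returns (net, sidecar dict, mean, std, velocities)."""
    with open(path + ".json") as fh:
        sidecar = json.load(fh)
    ncfg = dict(sidecar["network"])
    ncfg["depths"] = tuple(ncfg["depths"]) if ncfg.get("depths") else None
    net = build_network(NetworkConfig(**ncfg), seed=sidecar.get("seed", 0))
    data = np.load(path if path.endswith(".npz") else path + ".npz")
    state = {k: data[k] for k in data.files if not k.startswith("__")}
    net.load_state_dict(state)
    mean, std = data["__norm_mean"], data["__norm_std"]
    vels = [data[k] for k in sorted(data.files, key=lambda s: (len(s), s))
            if k.startswith("__vel_")]
    return net, sidecar, mean, std, vels


# ----------------------------------------------------------------- inference
def make_forward_fn(net: SegNetwork, mean, std):
    """Wrap a trained network + its normalization into the plain
    ``rgb HxWx3 -> (C, H/8, W/8) logits`` callable the multi-scale and WSI
    stages consume."""
    def forward(rgb: np.ndarray) -> np.ndarray:
        net.eval()
        with no_grad():
            out = net(normalize_image(rgb, mean, std)[None])
        return out.pl.data[0]
    return forward


def predict_tile(net: SegNetwork, image: np.ndarray, mean, std) -> np.ndarray:
    """Full-resolution class map for one RGB tile (eval mode)."""
    was_training = net.training
    net.eval()
    with no_grad():
        x = normalize_image(image, mean, std)[None]
        out = net(x)
        up = upsample_scores(out, image.shape[:2])
        pred = np.argmax(up.pl.data[0], axis=0).astype(np.uint8)
    net.train(was_training)
    return pred


def _validate(net, tiles, mean, std) -> float:
    """Dataset-level (pooled) mean IoU over the tumor classes, in [0, 1]."""
    rows = [iou_per_class(predict_tile(net, t.image, mean, std), t.mask)
            for t in tiles]
    return pooled_iou(rows).mean_pct / 100.0


def train_stage1(labeled: list[LabeledTile], unlabeled: list[np.ndarray],
                 cfg: Stage1Config, weights: LossWeights | None = None,
                 val: list[LabeledTile] | None = None,
                 resume_from: str | None = None,
                 log=None) -> str:
    """Train the network; returns the final checkpoint path (without .npz)."""
    if not labeled:
        raise ValueError("labeled set must be nonempty")
    if weights is None:
        weights = LossWeights(
            class_weights=inverse_frequency_weights([t.mask for t in labeled]))
    mean, std = dataset_stats([t.image for t in labeled])

    start_epoch = 0
    if resume_from:
        net, sidecar, mean, std, vels = load_checkpoint(resume_from)
        start_epoch = sidecar["epoch"]
        opt = SGD(net.parameters(), cfg.lr, cfg.momentum, cfg.weight_decay)
        for v, sv in zip(opt.velocity, vels):
            v[...] = sv
        net.train()
    else:
        net = build_network(cfg.network, seed=cfg.seed)
        net.train()
        opt = SGD(net.parameters(), cfg.lr, cfg.momentum, cfg.weight_decay)

    n_steps_per_epoch = max(1, len(labeled) // cfg.batch_labeled)
    total_steps = cfg.epochs * n_steps_per_epoch
    history = []
    final = os.path.join(cfg.checkpoint_dir, "stage1_final")
    for epoch in range(start_epoch, cfg.epochs):
        # per-epoch generator keyed by (seed, epoch) makes resume exact
        rng = np.random.default_rng((cfg.seed, epoch))
        order = rng.permutation(len(labeled))
        ep_report = {"Ls": 0.0, "Lu": 0.0}
        for step in range(n_steps_per_epoch):
            gstep = epoch * n_steps_per_epoch + step
            opt.lr = cfg.lr * (1.0 - gstep / total_steps) ** cfg.poly_power
            idx = order[step * cfg.batch_labeled:(step + 1) * cfg.batch_labeled]
            batch = _labeled_batch(labeled, idx, cfg.crop, cfg.scale_range,
                                   mean, std, rng)
            u_batch = []
            if unlabeled:
                u_idx = rng.integers(0, len(unlabeled), cfg.batch_unlabeled)
                u_batch = [unlabeled[i] for i in u_idx]
            report = stage1_step(net, batch, u_batch, weights, cfg, opt,
                                 mean, std, rng)
            ep_report["Ls"] += report["Ls"] / n_steps_per_epoch
            ep_report["Lu"] += report["Lu"] / n_steps_per_epoch
        ep_report["epoch"] = epoch + 1
        if val:
            ep_report["val_miou"] = _validate(net, val, mean, std)
        history.append(ep_report)
        if log:
            log(ep_report)
        if (epoch + 1) % cfg.checkpoint_every == 0 and epoch + 1 < cfg.epochs:
            save_checkpoint(os.path.join(cfg.checkpoint_dir, f"stage1_ep{epoch + 1}"),
                            net, cfg, epoch + 1, mean, std, opt)
    save_checkpoint(final, net, cfg, cfg.epochs, mean, std, opt,
                    extra={"history": history})
    return final
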