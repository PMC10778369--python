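"""Supervised and semi-supervised segmentation losses.

All functions accept probability maps either as plain numpy arrays or as
autodiff tensors (gradients flow through the predictions, never through
pseudo-labels), shaped ``(C, H, W)`` or ``(N, C, H, W)``.  Returned values
are scalar tensors; call ``.item()`` for the float.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import NetworkOutputs
from .nn import Tensor, as_tensor

__all__ = ["LossWeights", "weighted_ce", "boundary_bce", "bas_loss",
           "supervised_loss", "unimatch_loss"]


@dataclass(frozen=True)
class LossWeights:
    """Coefficients of the combined objective.

    lambda0/1/2/3 weight the detail-head CE, boundary BCE, main-head CE
    and boundary-aware CE; t gates the boundary-aware CE; tau, lambda_fp
    and mu parameterize the consistency loss on unlabeled batches.
    """

    lambda0: float = 0.4
    lambda1: float = 20.0
    lambda2: float = 1.0
    lambda3: float = 1.0
    t: float = 0.8
    tau: float = 0.95
    lambda_fp: float = 0.5
    mu: float = 0.5
    boundary_pos_weight: float = 1.0
    class_weights: tuple[float, ...] | None = None
    unlabeled_weight: float = 1.0

    def __post_init__(self):
        for name in ("lambda0", "lambda1", "lambda2", "lambda3", "lambda_fp",
                     "mu", "boundary_pos_weight", "unlabeled_weight"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 < self.t < 1.0:
            raise ValueError("t must be in (0, 1)")
        if not 0.0 < self.tau <= 1.0:
            raise ValueError("tau must be in (0, 1]")
        if self.class_weights is not None:
            cw = tuple(float(c) for c in self.class_weights)
            if any(c < 0 for c in cw):
                raise ValueError("class weights must be nonnegative")
            object.__setattr__(self, "class_weights", cw)


def _batched(x: Tensor | np.ndarray) -> Tensor:
    t = as_tensor(x)
    return t.reshape((1,) + t.shape) if t.ndim == 3 else t


def _onehot(gt: np.ndarray, num_classes: int) -> np.ndarray:
    gt = np.asarray(gt)
    if gt.max(initial=0) >= num_classes or gt.min(initial=0) < 0:
        raise ValueError("ground-truth class index out of range")
    eye = np.eye(num_classes)
    return np.moveaxis(eye[gt.astype(int)], -1, -3)  # (..., C, H, W)


def weighted_ce(pred_probs, gt: np.ndarray, class_weights=None) -> Tensor:
    """Mean over pixels of w_c * (-log p_true), probabilities clipped at 1e-12."""
    probs = _batched(pred_probs)
    n, c = probs.shape[:2]
    onehot = _onehot(np.broadcast_to(gt, (n,) + np.shape(gt)[-2:]), c)
    w = np.ones(c) if class_weights is None else np.asarray(class_weights, dtype=float)
    wmap = (onehot * w.reshape(1, c, 1, 1)).astype(probs.data.dtype)
    return -(probs.log() * wmap).sum() * (1.0 / (n * probs.shape[2] * probs.shape[3]))


def boundary_bce(plb_probs, gb: np.ndarray, pos_weight: float = 1.0) -> Tensor:
    """Weighted binary cross-entropy of the boundary head against the
    binary boundary target."""
    p = _batched(plb_probs)
    g = np.asarray(gb, dtype=float)
    if g.ndim == p.ndim - 1:
        g = g[:, None] if g.ndim == 3 else g[None]
    g = np.broadcast_to(g, p.shape)
    pos = (p.log() * (pos_weight * g))
    neg = ((1.0 - p).log() * (1.0 - g))
    return -(pos + neg).mean()


def bas_loss(pred_probs, gt, boundary_probs, t: float = 0.8,
             reduction: str = "sum") -> Tensor:
    """Boundary-aware cross-entropy: CE restricted to pixels where the
    boundary head exceeds ``t``.

    ``reduction='sum'`` matches the plain summed form; ``'mean_fired'``
    divides by the number of gated pixels (used inside the combined
    training objective so the term's scale is resolution-independent).
    """
    probs = _batched(pred_probs)
    n, c = probs.shape[:2]
    gt = np.asarray(gt)
    onehot = gt if gt.ndim == probs.ndim and gt.shape[-3] == c else _onehot(
        np.broadcast_to(gt, (n,) + gt.shape[-2:]), c)
    b = boundary_probs.data if isinstance(boundary_probs, Tensor) else np.asarray(boundary_probs)
    gate = (b > t).astype(probs.data.dtype)          # (N,1,H,W) or (1,H,W)
    gate = np.broadcast_to(gate.reshape(n, 1, *gate.shape[-2:]), probs.shape)
    term = -(probs.log() * (gate * np.asarray(onehot, dtype=float))).sum()
    if reduction == "sum":
        return term
    if reduction == "mean_fired":
        n_fired = max(1.0, float((b > t).sum()))
        return term * (1.0 / n_fired)
    raise ValueError(f"unknown reduction {reduction!r}")


def supervised_loss(outputs: NetworkOutputs, gs: np.ndarray, gb: np.ndarray,
                    w: LossWeights) -> tuple[Tensor, dict[str, float]]:
    """Combined supervised objective on full-resolution heads:
    lambda0*l0 + lambda1*l1 + lambda2*l2 + lambda3*l3 with l0 on the
    auxiliary head, l1 on the boundary head, l2 and l3 on the main head."""
    if outputs.pl.shape[-2:] != np.shape(gs)[-2:]:
        raise ValueError("heads must be upsampled to ground-truth resolution")
    probs_aux = outputs.pls.log_softmax(1).exp()
    probs_main = outputs.pl.log_softmax(1).exp()
    pb = outputs.plb.sigmoid()
    l0 = weighted_ce(probs_aux, gs, w.class_weights)
    l1 = boundary_bce(pb, gb, w.boundary_pos_weight)
    l2 = weighted_ce(probs_main, gs, w.class_weights)
    l3 = bas_loss(probs_main, gs, pb, w.t, reduction="mean_fired")
    total = w.lambda0 * l0 + w.lambda1 * l1 + w.lambda2 * l2 + w.lambda3 * l3
    comps = {"l0": l0.item(), "l1": l1.item(), "l2": l2.item(), "l3": l3.item()}
    return total, comps


def unimatch_loss(pw, pfp, ps1, ps2, w: LossWeights) -> Tensor:
    """Confidence-gated consistency loss over an unlabeled batch.

    The weak-view prediction ``pw`` acts as a frozen pseudo-label: pixels
    whose top confidence reaches ``tau`` contribute a cross-entropy
    between the hard pseudo-label and each perturbed prediction, weighted
    lambda_fp for the feature-perturbed view and mu/2 for each strong view.
    """
    pw = pw.data if isinstance(pw, Tensor) else np.asarray(pw)
    if pw.ndim == 3:
        pw = pw[None]
    pfp, ps1, ps2 = _batched(pfp), _batched(ps1), _batched(ps2)
    n, c, h, ww = pfp.shape
    conf = pw.max(axis=1, keepdims=True)
    gate = (conf >= w.tau).astype(pfp.data.dtype)          # (N,1,H,W)
    hard = _onehot(pw.argmax(axis=1), c)                   # (N,C,H,W)
    sel = (gate * hard).astype(pfp.data.dtype)

    def ce(p: Tensor) -> Tensor:
        return -(p.log() * sel).sum(axis=(1, 2, 3)) * (1.0 / (h * ww))

    per_item = w.lambda_fp * ce(pfp) + (w.mu / 2.0) * (ce(ps1) + ce(ps2))
    return per_item.sum() * (1.0 / n)
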