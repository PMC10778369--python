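"""Segmentation metrics, stratified reporting, and cross-validation splits."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["IoURow", "IoUReport", "iou_per_class", "pooled_iou",
           "stratified_eval", "crossval_split"]

TUMOR_CLASSES = (1, 2)
CLASS_NAMES = {1: "dcis", 2: "ic"}


@dataclass
class IoURow:
    """Per-tile IoU in percent; NaN for a class absent from both maps."""

    iou_pct: dict[int, float]
    intersections: dict[int, int]
    unions: dict[int, int]
    stain: str | None = None
    tumor_type: str | None = None

    @property
    def mean_pct(self) -> float:
        vals = [v for v in self.iou_pct.values() if not np.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")


@dataclass
class IoUReport:
    iou_dcis_pct: float
    iou_ic_pct: float
    mean_pct: float
    per_tile: list[IoURow] = field(default_factory=list)


def iou_per_class(pred: np.ndarray, gt: np.ndarray,
                  classes: tuple[int, ...] = TUMOR_CLASSES, **meta) -> IoURow:
    pred, gt = np.asarray(pred), np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError("prediction and ground truth shapes differ")
    ious, inters, unions = {}, {}, {}
    for c in classes:
        p, g = pred == c, gt == c
        inter = int((p & g).sum())
        union = int((p | g).sum())
        inters[c], unions[c] = inter, union
        ious[c] = 100.0 * inter / union if union else float("nan")
    return IoURow(ious, inters, unions, **meta)


def pooled_iou(rows: list[IoURow], classes: tuple[int, ...] = TUMOR_CLASSES) -> IoUReport:
    """Dataset-level IoU from the pooled confusion counts (headline metric);
    per-tile rows are kept alongside."""
    ious = {}
    for c in classes:
        inter = sum(r.intersections[c] for r in rows)
        union = sum(r.unions[c] for r in rows)
        ious[c] = 100.0 * inter / union if union else float("nan")
    vals = [v for v in ious.values() if not np.isnan(v)]
    return IoUReport(iou_dcis_pct=ious.get(1, float("nan")),
                     iou_ic_pct=ious.get(2, float("nan")),
                     mean_pct=float(np.mean(vals)) if vals else float("nan"),
                     per_tile=rows)


def stratified_eval(rows: list[IoURow]) -> pd.DataFrame:
    """Mean per-tile IoU per (stain x class) cell with counts; strata with
    no tiles are simply absent from the table."""
    records = []
    for r in rows:
        if r.stain is None or r.tumor_type is None:
            raise ValueError("every tile needs stain and tumor-type metadata")
        for c, v in r.iou_pct.items():
            if not np.isnan(v):
                records.append({"stain": r.stain, "tumor_type": r.tumor_type,
                                "class": CLASS_NAMES.get(c, str(c)), "iou_pct": v})
    if not records:
        return pd.DataFrame(columns=["stain", "class", "mean_iou_pct", "n_tiles"])
    df = pd.DataFrame(records)
    out = (df.groupby(["stain", "class"])["iou_pct"]
             .agg(mean_iou_pct="mean", n_tiles="size").reset_index())
    return out


def crossval_split(items: list, k: int, seed: int, group_key=None) -> list[list]:
    """Split ``items`` into k folds grouped by case id (no case straddles
    folds).  ``group_key(item)`` defaults to the item itself."""
    group_key = group_key or (lambda x: x)
    cases: dict = {}
    for it in items:
        cases.setdefault(group_key(it), []).append(it)
    case_ids = sorted(cases, key=str)
    if k > len(case_ids):
        raise ValueError(f"k={k} exceeds number of cases ({len(case_ids)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(case_ids))
    folds: list[list] = [[] for _ in range(k)]
    for pos, ci in enumerate(order):
        folds[pos % k].extend(cases[case_ids[ci]])
    return folds
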