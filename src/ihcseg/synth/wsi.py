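"""Pseudo whole-slide images with an exact nucleus ledger.

A pseudo-WSI is a large labeled canvas assembled from the same nest
primitives as single tiles, plus per-nucleus ground truth so that
marker-index recovery can be checked against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .stains import DEFAULT_STAINS, render_rgb
from .tiles import (CLASS_BACKGROUND, CLASS_DCIS, CLASS_IC, NestRecord,
                    NucleusClass, NucleusTruth, Stain, _blob_mask, _disk,
                    _place_centers, _render_nucleus, _scatter_nuclei)

__all__ = ["WsiSpec", "PseudoWSI", "generate_pseudo_wsi"]


@dataclass(frozen=True)
class WsiSpec:
    width: int = 1280
    height: int = 1280
    stain: Stain = Stain.KI67
    positivity_ic: float = 0.35
    positivity_dcis: float = 0.15
    n_dcis_nests: int = 3
    n_ic_clusters: int = 2
    n_lymph_aggregates: int = 2
    n_lobules: int = 1
    context_side: int = 512
    seed: int = 0

    def __post_init__(self):
        if min(self.width, self.height) < 2 * self.context_side:
            raise ValueError("pseudo-WSI must be at least 2x the context "
                             "window per side")
        for p in (self.positivity_ic, self.positivity_dcis):
            if not 0.0 <= p <= 1.0:
                raise ValueError("positivity must be in [0, 1]")
        object.__setattr__(self, "stain", Stain(self.stain))


@dataclass
class PseudoWSI:
    image: np.ndarray                   # H x W x 3 uint8
    mask: np.ndarray                    # H x W uint8 {0,1,2}
    nuclei: list[NucleusTruth]
    placement_log: list[NestRecord] = field(default_factory=list)

    def _index(self, keep) -> float:
        pos = sum(1 for n in self.nuclei if keep(n) and n.marker_positive)
        tot = sum(1 for n in self.nuclei if keep(n))
        return 100.0 * pos / tot if tot else float("nan")

    @property
    def true_index_ic(self) -> float:
        return self._index(lambda n: n.nucleus_class is NucleusClass.TUMOR_IC)

    @property
    def true_index_tumor(self) -> float:
        return self._index(lambda n: n.nucleus_class in
                           (NucleusClass.TUMOR_IC, NucleusClass.TUMOR_DCIS))

    @property
    def true_index_overall(self) -> float:
        return self._index(lambda n: True)

    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for n in self.nuclei:
            out[n.nucleus_class.value] = out.get(n.nucleus_class.value, 0) + 1
        return out


def generate_pseudo_wsi(spec: WsiSpec) -> PseudoWSI:
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    size = (h, w)
    membrane = spec.stain == Stain.HER2

    noise = ndimage.gaussian_filter(rng.normal(0, 1, size), 8)
    nrange = noise.max() - noise.min()
    if nrange > 0:
        noise = (noise - noise.min()) / nrange
    c_hema = 0.05 + 0.05 * noise
    c_dab = np.zeros(size)
    mask = np.zeros(size, dtype=np.uint8)
    nuclei: list[NucleusTruth] = []
    log: list[NestRecord] = []
    occupied: list[tuple[float, float, float]] = []

    def render_nest(cy, cx, r, klass, positivity):
        if klass == CLASS_DCIS:
            blob = _blob_mask(size, cy, cx, r, rng, 0.08, (2, 3))
        else:
            blob = _blob_mask(size, cy, cx, r, rng, 0.30, (5, 7, 9, 11))
        blob &= mask == 0
        mask[blob] = klass
        log.append(NestRecord(klass, (cy, cx), r, int(blob.sum())))
        c_hema[blob] = np.maximum(c_hema[blob], 0.22)
        if klass == CLASS_DCIS:
            rim = blob & ~ndimage.binary_erosion(blob, iterations=2)
            c_hema[rim] = np.maximum(c_hema[rim], 0.85)
            interior = ndimage.binary_erosion(blob, iterations=4)
            ncls = NucleusClass.TUMOR_DCIS
        else:
            interior = ndimage.binary_erosion(blob, iterations=1)
            ncls = NucleusClass.TUMOR_IC
        for (ny, nx) in _scatter_nuclei(rng, interior, spacing=9.0):
            pos = bool(rng.random() < positivity)
            _render_nucleus(c_hema, c_dab, size, ny, nx,
                            rng.uniform(2.2, 3.2), pos, membrane, rng)
            nuclei.append(NucleusTruth(nx, ny, ncls, pos))

    # large in-situ nests
    for cy, cx, r in _place_centers(rng, size, spec.n_dcis_nests,
                                    lambda: rng.uniform(60, 95), occupied,
                                    margin=12.0):
        render_nest(cy, cx, r, CLASS_DCIS, spec.positivity_dcis)
        occupied.append((cy, cx, r))

    # invasive clusters: many small nests scattered over a wide area so they
    # routinely straddle inference-core borders
    for ccy, ccx, cr in _place_centers(rng, size, spec.n_ic_clusters,
                                       lambda: rng.uniform(120, 190), occupied,
                                       margin=10.0):
        occupied.append((ccy, ccx, cr))
        n_nests = int(rng.integers(8, 14))
        local: list[tuple[float, float, float]] = []
        for _ in range(n_nests):
            r = rng.uniform(10, 24)
            for _ in range(200):
                cy = ccy + rng.uniform(-cr + r, cr - r)
                cx = ccx + rng.uniform(-cr + r, cr - r)
                if not (r + 2 < cy < h - r - 2 and r + 2 < cx < w - r - 2):
                    continue
                if all(np.hypot(cy - oy, cx - ox) > r + orr + 4 for oy, ox, orr in local):
                    local.append((cy, cx, r))
                    render_nest(cy, cx, r, CLASS_IC, spec.positivity_ic)
                    break

    # confounders (background class, marker negative)
    for cy, cx, r in _place_centers(rng, size, spec.n_lymph_aggregates,
                                    lambda: rng.uniform(35, 60), occupied,
                                    margin=8.0):
        occupied.append((cy, cx, r))
        blob = _blob_mask(size, cy, cx, r, rng, 0.2, (3, 5)) & (mask == 0)
        c_hema[blob] = np.maximum(c_hema[blob], 0.15)
        for (ny, nx) in _scatter_nuclei(rng, blob, spacing=7.0):
            _render_nucleus(c_hema, c_dab, size, ny, nx,
                            rng.uniform(1.6, 2.2), False, False, rng)
            nuclei.append(NucleusTruth(nx, ny, NucleusClass.LYMPHOCYTE, False))
        log.append(NestRecord(CLASS_BACKGROUND, (cy, cx), r, int(blob.sum()),
                              "lymphocytes"))
    for cy, cx, r in _place_centers(rng, size, spec.n_lobules,
                                    lambda: rng.uniform(22, 32), occupied,
                                    margin=8.0):
        occupied.append((cy, cx, r))
        n_px = 0
        for _ in range(int(rng.integers(5, 9))):
            acy = cy + rng.uniform(-r * 0.6, r * 0.6)
            acx = cx + rng.uniform(-r * 0.6, r * 0.6)
            acinus = _disk(size, acy, acx, rng.uniform(4, 7)) & (mask == 0)
            n_px += int(acinus.sum())
            c_hema[acinus] = np.maximum(c_hema[acinus], 0.30)
            for (ny, nx) in _scatter_nuclei(rng, acinus, spacing=6.0):
                _render_nucleus(c_hema, c_dab, size, ny, nx, 2.0, False, False, rng)
                nuclei.append(NucleusTruth(nx, ny,
                                           NucleusClass.NORMAL_EPITHELIAL, False))
        log.append(NestRecord(CLASS_BACKGROUND, (cy, cx), r, n_px, "lobule"))

    image = render_rgb(c_hema, c_dab, DEFAULT_STAINS)
    return PseudoWSI(image=image, mask=mask, nuclei=nuclei, placement_log=log)
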