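"""Procedural generation of labeled IHC-like image tiles.

Tumor regions are rendered as epithelial nests over a faint stromal
background.  In-situ nests are large and rounded with a dark continuous
rim (a stand-in for the myoepithelial layer); invasive nests are small
with jagged perimeters.  Normal lobules and lymphocyte aggregates can be
added as background-class confounders.  Nuclei carry a known
positive/negative marker label realized through the H-DAB forward model.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .stains import DEFAULT_STAINS, StainVectors, render_rgb

__all__ = [
    "Stain", "Scenario", "TileSpec", "NucleusTruth", "NestRecord",
    "LabeledTile", "generate_tile", "derive_boundary_gt",
    "CLASS_BACKGROUND", "CLASS_DCIS", "CLASS_IC",
]

CLASS_BACKGROUND = 0
CLASS_DCIS = 1
CLASS_IC = 2

DEFAULT_BOUNDARY_WIDTH = 2


class Stain(str, enum.Enum):
    ER = "ER"
    PR = "PR"
    HER2 = "HER2"
    KI67 = "Ki67"


class Scenario(str, enum.Enum):
    NORMAL = "normal"
    DCIS = "dcis"
    INVASIVE = "invasive"
    MIXED = "mixed"


class NucleusClass(str, enum.Enum):
    TUMOR_DCIS = "tumor_dcis"
    TUMOR_IC = "tumor_ic"
    LYMPHOCYTE = "lymphocyte"
    NORMAL_EPITHELIAL = "normal_epithelial"


@dataclass(frozen=True)
class TileSpec:
    size_px: int = 256
    stain: Stain = Stain.KI67
    positivity: float = 0.3
    scenario: Scenario = Scenario.MIXED
    nest_size_range: tuple[int, int] = (10, 22)
    dcis_radius_range: tuple[int, int] = (34, 58)
    confounders: frozenset = frozenset()
    seed: int = 0

    def __post_init__(self):
        if self.size_px < 64 or self.size_px % 8 != 0:
            raise ValueError("size_px must be >= 64 and divisible by 8")
        if not 0.0 <= self.positivity <= 1.0:
            raise ValueError("positivity must be in [0, 1]")
        for rng_ in (self.nest_size_range, self.dcis_radius_range):
            if rng_[0] <= 0 or rng_[1] < rng_[0]:
                raise ValueError("radius ranges need positive, ordered bounds")
        object.__setattr__(self, "stain", Stain(self.stain))
        object.__setattr__(self, "scenario", Scenario(self.scenario))
        object.__setattr__(self, "confounders", frozenset(self.confounders))
        bad = self.confounders - {"lobule", "lymphocytes"}
        if bad:
            raise ValueError(f"unknown confounders: {sorted(bad)}")


@dataclass
class NucleusTruth:
    x: float
    y: float
    nucleus_class: NucleusClass
    marker_positive: bool


@dataclass
class NestRecord:
    """Placement-log entry: one rasterized nest."""

    nest_class: int           # CLASS_DCIS or CLASS_IC (0 for confounders)
    center: tuple[float, float]
    radius: float
    n_pixels: int             # pixels this nest contributed to the mask
    kind: str = "nest"        # nest | lobule | lymphocytes


@dataclass
class LabeledTile:
    image: np.ndarray         # H x W x 3 uint8
    mask: np.ndarray          # H x W uint8, values {0, 1, 2}
    boundary: np.ndarray      # H x W uint8 binary
    stain: Stain
    scenario: Scenario
    nuclei: list[NucleusTruth] = field(default_factory=list)
    placement_log: list[NestRecord] = field(default_factory=list)

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError("image and mask dimensions disagree")
        if not np.isin(self.mask, [0, 1, 2]).all():
            raise ValueError("mask values must be in {0, 1, 2}")


# --------------------------------------------------------------------- shapes
def _as_shape(shape) -> tuple[int, int]:
    return (shape, shape) if isinstance(shape, int) else tuple(shape)


def _blob_mask(shape, cy: float, cx: float, radius: float,
               rng: np.random.Generator, jaggedness: float,
               harmonics: tuple[int, ...]) -> np.ndarray:
    """Rasterize a star-convex blob: r(theta) = R(1 + jaggedness * sum sin)."""
    h, w = _as_shape(shape)
    amps = rng.uniform(0.4, 1.0, len(harmonics))
    phases = rng.uniform(0, 2 * np.pi, len(harmonics))
    pad = int(radius * (1 + jaggedness) + 3)
    y0, y1 = max(0, int(cy) - pad), min(h, int(cy) + pad + 1)
    x0, x1 = max(0, int(cx) - pad), min(w, int(cx) + pad + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    rad = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    pert = np.zeros_like(theta)
    for a, ph, hh in zip(amps, phases, harmonics):
        pert += a * np.sin(hh * theta + ph)
    pert /= max(1.0, np.sum(amps))
    rlim = radius * (1.0 + jaggedness * pert)
    local = rad <= rlim
    out = np.zeros((h, w), dtype=bool)
    out[y0:y1, x0:x1] = local
    return out


def _disk(shape, cy: float, cx: float, r: float) -> np.ndarray:
    h, w = _as_shape(shape)
    pad = int(r) + 2
    y0, y1 = max(0, int(cy) - pad), min(h, int(cy) + pad + 1)
    x0, x1 = max(0, int(cx) - pad), min(w, int(cx) + pad + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    out = np.zeros((h, w), dtype=bool)
    out[y0:y1, x0:x1] = np.hypot(yy - cy, xx - cx) <= r
    return out


def _place_centers(rng: np.random.Generator, shape, n: int, radius_fn,
                   occupied: list[tuple[float, float, float]],
                   margin: float = 5.0, tries: int = 300):
    """Rejection-sample non-overlapping (cy, cx, r) triples."""
    h, w = _as_shape(shape)
    placed = []
    for _ in range(n):
        r = radius_fn()
        for _ in range(tries):
            cy = rng.uniform(r + 2, h - r - 2)
            cx = rng.uniform(r + 2, w - r - 2)
            if all(np.hypot(cy - oy, cx - ox) > r + orr + margin
                   for oy, ox, orr in occupied + placed):
                placed.append((cy, cx, r))
                break
    return placed


# -------------------------------------------------------------------- nuclei
def _scatter_nuclei(rng: np.random.Generator, region: np.ndarray, spacing: float,
                    exclude: np.ndarray | None = None) -> list[tuple[float, float]]:
    """Poisson-disk-ish nucleus centers inside a boolean region."""
    ys, xs = np.nonzero(region if exclude is None else region & ~exclude)
    if len(ys) == 0:
        return []
    order = rng.permutation(len(ys))
    pts: list[tuple[float, float]] = []
    grid: dict[tuple[int, int], list[tuple[float, float]]] = {}
    cell = spacing
    for i in order:
        y, x = float(ys[i]), float(xs[i])
        key = (int(y // cell), int(x // cell))
        ok = True
        for ky in range(key[0] - 1, key[0] + 2):
            for kx in range(key[1] - 1, key[1] + 2):
                for py, px in grid.get((ky, kx), ()):
                    if (y - py) ** 2 + (x - px) ** 2 < spacing ** 2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            pts.append((y, x))
            grid.setdefault(key, []).append((y, x))
    return pts


def _render_nucleus(c_hema, c_dab, size, y, x, r, positive, membrane,
                    rng: np.random.Generator):
    """Draw one nucleus onto the concentration maps."""
    core = _disk(size, y, x, r)
    if positive and not membrane:
        # nuclear chromogen: strong DAB, faint hematoxylin
        c_dab[core] = np.maximum(c_dab[core], rng.uniform(0.85, 1.05))
        c_hema[core] = np.maximum(c_hema[core], 0.15)
    else:
        c_hema[core] = np.maximum(c_hema[core], rng.uniform(0.75, 0.95))
    if positive and membrane:
        ring = _disk(size, y, x, r + 2.0) & ~_disk(size, y, x, r + 0.5)
        c_dab[ring] = np.maximum(c_dab[ring], rng.uniform(0.75, 0.95))


# ------------------------------------------------------------------ boundary
def derive_boundary_gt(mask: np.ndarray, width_px: int = DEFAULT_BOUNDARY_WIDTH) -> np.ndarray:
    """Binary boundary target: class-transition pixels (4-neighborhood)
    thickened to ``width_px`` by Chebyshev dilation (distance < width_px).

    width_px=1 marks exactly the transition pixels, so a straight edge
    yields a band 2*width_px pixels across (both sides of the edge).
    """
    mask = np.asarray(mask)
    if not np.isin(mask, [0, 1, 2]).all():
        raise ValueError("mask values must be in {0, 1, 2}")
    if width_px < 1:
        raise ValueError("width_px must be >= 1")
    trans = np.zeros(mask.shape, dtype=bool)
    trans[:-1, :] |= mask[:-1, :] != mask[1:, :]
    trans[1:, :] |= mask[1:, :] != mask[:-1, :]
    trans[:, :-1] |= mask[:, :-1] != mask[:, 1:]
    trans[:, 1:] |= mask[:, 1:] != mask[:, :-1]
    if width_px > 1:
        k = 2 * (width_px - 1) + 1
        trans = ndimage.maximum_filter(trans, size=k, mode="constant")
    return trans.astype(np.uint8)


# ----------------------------------------------------------------- generator
def generate_tile(spec: TileSpec, boundary_width: int = DEFAULT_BOUNDARY_WIDTH) -> LabeledTile:
    """Render one labeled tile; deterministic for a fixed spec (incl. seed)."""
    rng = np.random.default_rng(spec.seed)
    size = spec.size_px
    membrane = spec.stain == Stain.HER2

    # stromal background with smooth texture
    noise = ndimage.gaussian_filter(rng.normal(0, 1, (size, size)), 6)
    nrange = noise.max() - noise.min()
    if nrange > 0:
        noise = (noise - noise.min()) / nrange
    c_hema = 0.05 + 0.05 * noise
    c_dab = np.zeros((size, size))

    mask = np.zeros((size, size), dtype=np.uint8)
    log: list[NestRecord] = []
    nuclei: list[NucleusTruth] = []
    occupied: list[tuple[float, float, float]] = []

    scale = size / 256.0
    n_dcis, n_ic = {
        Scenario.NORMAL: (0, 0),
        Scenario.DCIS: (1 + int(rng.integers(0, 2)), 0),
        Scenario.INVASIVE: (0, 4 + int(rng.integers(0, 4))),
        Scenario.MIXED: (1, 3 + int(rng.integers(0, 3))),
    }[spec.scenario]
    n_dcis = max(n_dcis, 0)
    if spec.scenario is Scenario.MIXED:
        n_dcis, n_ic = max(1, n_dcis), max(1, n_ic)

    def add_nest(cy, cx, r, klass):
        if klass == CLASS_DCIS:
            blob = _blob_mask(size, cy, cx, r, rng, 0.08, (2, 3))
        else:
            blob = _blob_mask(size, cy, cx, r, rng, 0.30, (5, 7, 9, 11))
        blob &= mask == 0
        mask[blob] = klass
        log.append(NestRecord(klass, (cy, cx), r, int(blob.sum())))
        # cytoplasm
        c_hema[blob] = np.maximum(c_hema[blob], 0.22 + 0.05 * noise[blob])
        if klass == CLASS_DCIS:
            rim = blob & ~ndimage.binary_erosion(blob, iterations=2)
            c_hema[rim] = np.maximum(c_hema[rim], 0.85)
            interior = ndimage.binary_erosion(blob, iterations=4)
        else:
            interior = ndimage.binary_erosion(blob, iterations=1)
        ncls = NucleusClass.TUMOR_DCIS if klass == CLASS_DCIS else NucleusClass.TUMOR_IC
        for (ny, nx) in _scatter_nuclei(rng, interior, spacing=9.0):
            pos = bool(rng.random() < spec.positivity)
            _render_nucleus(c_hema, c_dab, size, ny, nx,
                            rng.uniform(2.2, 3.2), pos, membrane, rng)
            nuclei.append(NucleusTruth(nx, ny, ncls, pos))

    dcis_lo = min(spec.dcis_radius_range[0] * scale, size / 3.2)
    dcis_hi = min(spec.dcis_radius_range[1] * scale, size / 2.8)
    if spec.scenario is Scenario.MIXED:
        # leave room so invasive nests can always be placed alongside
        dcis_hi = min(dcis_hi, size / 3.5)
        dcis_lo = min(dcis_lo, dcis_hi)
    for cy, cx, r in _place_centers(
            rng, size, n_dcis, lambda: rng.uniform(dcis_lo, dcis_hi), occupied):
        add_nest(cy, cx, r, CLASS_DCIS)
        occupied.append((cy, cx, r))
    for cy, cx, r in _place_centers(
            rng, size, n_ic,
            lambda: rng.uniform(spec.nest_size_range[0] * scale,
                                spec.nest_size_range[1] * scale),
            occupied, margin=4.0):
        add_nest(cy, cx, r, CLASS_IC)
        occupied.append((cy, cx, r))

    # background-class confounders
    if "lobule" in spec.confounders or spec.scenario is Scenario.NORMAL:
        for cy, cx, r in _place_centers(rng, size, 1, lambda: rng.uniform(18, 26) * scale,
                                        occupied):
            occupied.append((cy, cx, r))
            n_px = 0
            for _ in range(int(rng.integers(5, 9))):
                acy = cy + rng.uniform(-r * 0.6, r * 0.6)
                acx = cx + rng.uniform(-r * 0.6, r * 0.6)
                acinus = _disk(size, acy, acx, rng.uniform(4, 7))
                acinus &= mask == 0
                n_px += int(acinus.sum())
                c_hema[acinus] = np.maximum(c_hema[acinus], 0.30)
                for (ny, nx) in _scatter_nuclei(rng, acinus, spacing=6.0):
                    _render_nucleus(c_hema, c_dab, size, ny, nx, 2.0, False,
                                    False, rng)
                    nuclei.append(NucleusTruth(nx, ny,
                                               NucleusClass.NORMAL_EPITHELIAL, False))
            log.append(NestRecord(CLASS_BACKGROUND, (cy, cx), r, n_px, "lobule"))
    if "lymphocytes" in spec.confounders:
        for cy, cx, r in _place_centers(rng, size, 1, lambda: rng.uniform(20, 30) * scale,
                                        occupied):
            occupied.append((cy, cx, r))
            blob = _blob_mask(size, cy, cx, r, rng, 0.2, (3, 5)) & (mask == 0)
            c_hema[blob] = np.maximum(c_hema[blob], 0.15)
            for (ny, nx) in _scatter_nuclei(rng, blob, spacing=7.0):
                _render_nucleus(c_hema, c_dab, size, ny, nx,
                                rng.uniform(1.6, 2.2), False, False, rng)
                nuclei.append(NucleusTruth(nx, ny, NucleusClass.LYMPHOCYTE, False))
            log.append(NestRecord(CLASS_BACKGROUND, (cy, cx), r,
                                  int(blob.sum()), "lymphocytes"))

    image = render_rgb(c_hema, c_dab, DEFAULT_STAINS)
    boundary = derive_boundary_gt(mask, boundary_width)
    return LabeledTile(image=image, mask=mask, boundary=boundary,
                       stain=spec.stain, scenario=spec.scenario,
                       nuclei=nuclei, placement_log=log)
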