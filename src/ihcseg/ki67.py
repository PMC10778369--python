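"""Mask-conditioned Ki-67 quantification.

Color-deconvolve H-DAB tiles into optical-density channels, detect nuclei
on the combined nuclear OD, call each detection chromogen-positive or
-negative by mean DAB OD, and score the positive fraction inside a chosen
mask condition.  Agreement statistics (Pearson r, mean/SD of errors in
percentage points) compare estimated against reference indices.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.stats import pearsonr
from skimage.feature import peak_local_max
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .synth.stains import DEFAULT_STAINS, StainVectors, rgb_to_od
from .wsi_inference import LabelMask

__all__ = ["MaskCondition", "DetectionParams", "NucleusDetection", "Ki67Result",
           "AgreementStats", "UndefinedIndexError", "od_deconvolve",
           "detect_nuclei", "ki67_index", "summarize_agreement"]


class MaskCondition(str, enum.Enum):
    NO_MASK = "no_mask"
    TUMOR_MASK = "tumor_mask"
    IC_MASK = "ic_mask"


_CONDITION_CLASSES = {
    MaskCondition.NO_MASK: None,
    MaskCondition.TUMOR_MASK: (1, 2),
    MaskCondition.IC_MASK: (2,),
}


class UndefinedIndexError(ValueError):
    """Raised when no detections fall inside the scored region."""


@dataclass(frozen=True)
class DetectionParams:
    sigma: float = 1.0            # gaussian smoothing of the nuclear OD
    threshold: float = 0.45       # nuclear OD threshold
    min_area: int = 5
    max_area: int = 250
    min_compactness: float = 0.4  # 4*pi*A/P^2; rejects rim fragments
    use_watershed: bool = True
    min_distance: int = 4         # peak separation for the watershed split
    dab_threshold: float = 0.2    # mean DAB OD above which a nucleus is positive


@dataclass
class NucleusDetection:
    x: float
    y: float
    area: int
    mean_dab_od: float
    mean_hema_od: float
    positive: bool


@dataclass
class Ki67Result:
    condition: MaskCondition
    n_positive: int
    n_negative: int

    @property
    def index_pct(self) -> float:
        total = self.n_positive + self.n_negative
        if total == 0:
            raise UndefinedIndexError("no tumor-cell detections in region")
        return 100.0 * self.n_positive / total


@dataclass
class AgreementStats:
    pearson_r: float
    mean_error: float   # estimate - reference, percentage points
    sd_error: float     # sample SD (ddof=1)
    n: int


def od_deconvolve(rgb_tile: np.ndarray,
                  vectors: StainVectors = DEFAULT_STAINS) -> dict[str, np.ndarray]:
    """Project per-pixel optical density onto the stain basis.

    Returns nonnegative concentration maps keyed 'hematoxylin', 'dab',
    'residual'.
    """
    od = rgb_to_od(rgb_tile)
    minv = np.linalg.inv(vectors.matrix())
    conc = od @ minv
    conc = np.clip(conc, 0.0, None)
    return {"hematoxylin": conc[..., 0], "dab": conc[..., 1],
            "residual": conc[..., 2]}


def detect_nuclei(od_maps: dict[str, np.ndarray],
                  params: DetectionParams = DetectionParams()) -> list[NucleusDetection]:
    """Segment nuclei from the combined nuclear OD and call positivity.

    Pipeline: smooth, threshold, optional distance-transform watershed to
    split touching nuclei, then filter by area and compactness.
    """
    hema, dab = od_maps["hematoxylin"], od_maps["dab"]
    nuclear = ndimage.gaussian_filter(hema + dab, params.sigma)
    fg = nuclear > params.threshold
    if not fg.any():
        return []
    if params.use_watershed:
        dist = ndimage.distance_transform_edt(fg)
        peaks = peak_local_max(dist, min_distance=params.min_distance,
                               labels=fg, exclude_border=False)
        markers = np.zeros(fg.shape, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        if markers.max() == 0:
            labels, _ = ndimage.label(fg)
        else:
            labels = watershed(-dist, markers, mask=fg)
    else:
        labels, _ = ndimage.label(fg)

    detections = []
    for prop in regionprops(labels):
        if not params.min_area <= prop.area <= params.max_area:
            continue
        compactness = 4.0 * np.pi * prop.area / max(prop.perimeter, 1.0) ** 2
        if compactness < params.min_compactness:
            continue
        region = labels == prop.label
        mean_dab = float(dab[region].mean())
        mean_hema = float(hema[region].mean())
        cy, cx = prop.centroid
        detections.append(NucleusDetection(
            x=float(cx), y=float(cy), area=int(prop.area),
            mean_dab_od=mean_dab, mean_hema_od=mean_hema,
            positive=mean_dab > params.dab_threshold))
    return detections


def _level0_mask(mask, shape_hw) -> np.ndarray:
    if isinstance(mask, LabelMask):
        return mask.to_level0(shape_hw)
    return np.asarray(mask)


def ki67_index(detections: list[NucleusDetection], mask,
               condition: MaskCondition | str,
               image_shape_hw: tuple[int, int] | None = None) -> Ki67Result:
    """Count positive/negative detections inside the region selected by
    ``condition``; membership is tested at the detection centroid.

    ``mask`` may be None (no_mask only), a level-0 class map, or a
    LabelMask (upsampled nearest; requires ``image_shape_hw``).
    """
    condition = MaskCondition(condition)
    classes = _CONDITION_CLASSES[condition]
    if classes is None:
        included = detections
    else:
        if mask is None:
            raise ValueError(f"{condition.value} requires a class mask")
        if isinstance(mask, LabelMask):
            if image_shape_hw is None:
                raise ValueError("image_shape_hw needed to upsample a LabelMask")
            mask = mask.to_level0(image_shape_hw)
        mask = np.asarray(mask)
        included = []
        for d in detections:
            r, c = int(round(d.y)), int(round(d.x))
            if 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] \
                    and mask[r, c] in classes:
                included.append(d)
    n_pos = sum(1 for d in included if d.positive)
    n_neg = len(included) - n_pos
    result = Ki67Result(condition, n_pos, n_neg)
    _ = result.index_pct  # raises UndefinedIndexError when empty
    return result


def summarize_agreement(estimates, references) -> AgreementStats:
    est = np.asarray(estimates, dtype=np.float64)
    ref = np.asarray(references, dtype=np.float64)
    if est.shape != ref.shape or est.ndim != 1:
        raise ValueError("estimates and references must be paired 1-D vectors")
    if len(est) < 3:
        raise ValueError("need at least 3 paired cases")
    if est.std() == 0 or ref.std() == 0:
        raise ValueError("zero variance makes the correlation undefined")
    r = float(pearsonr(est, ref).statistic)
    errors = est - ref
    return AgreementStats(pearson_r=r, mean_error=float(errors.mean()),
                          sd_error=float(errors.std(ddof=1)), n=len(est))
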