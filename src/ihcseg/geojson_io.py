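"""GeoJSON export of class masks (QuPath-compatible FeatureCollection):
one polygon feature per connected component, class name in properties."""

from __future__ import annotations

import json

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon, mapping
from skimage import measure

__all__ = ["mask_to_geojson", "write_geojson"]

_CLASS_NAMES = {1: "DCIS", 2: "IC"}


def mask_to_geojson(mask: np.ndarray, scale: float = 1.0,
                    class_names: dict[int, str] | None = None) -> dict:
    """Trace each connected component of each non-background class into a
    polygon; coordinates are (x, y) level-0 pixels (``scale`` multiplies
    them, e.g. 8 for a stride-8 mask)."""
    class_names = class_names or _CLASS_NAMES
    features = []
    for cls, name in class_names.items():
        binary = mask == cls
        if not binary.any():
            continue
        labeled, n = ndimage.label(binary)
        for comp in range(1, n + 1):
            comp_mask = np.pad(labeled == comp, 1)  # close contours at edges
            for contour in measure.find_contours(comp_mask.astype(float), 0.5):
                if len(contour) < 4:
                    continue
                xy = [((c - 1.0) * scale, (r - 1.0) * scale) for r, c in contour]
                poly = Polygon(xy)
                if not poly.is_valid:
                    poly = poly.buffer(0)
                if poly.is_empty or poly.area == 0:
                    continue
                features.append({
                    "type": "Feature",
                    "geometry": mapping(poly),
                    "properties": {
                        "objectType": "annotation",
                        "classification": {"name": name},
                    },
                })
    return {"type": "FeatureCollection", "features": features}


def write_geojson(mask: np.ndarray, path: str, scale: float = 1.0) -> None:
    with open(path, "w") as fh:
        json.dump(mask_to_geojson(mask, scale), fh)
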