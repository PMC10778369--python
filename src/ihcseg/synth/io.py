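"""File I/O for synthetic artifacts: paired PNG tiles, nucleus ledgers,
and tiled-TIFF pseudo-WSIs."""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .tiles import LabeledTile, NucleusTruth, NucleusClass, Scenario, Stain
from .wsi import PseudoWSI

__all__ = ["write_tile", "read_tile_pair", "write_ledger", "read_ledger",
           "write_pseudo_wsi", "read_pseudo_wsi"]


def write_tile(tile: LabeledTile, out_dir: str, stem: str) -> tuple[str, str]:
    os.makedirs(out_dir, exist_ok=True)
    img_path = os.path.join(out_dir, f"{stem}.png")
    mask_path = os.path.join(out_dir, f"{stem}_mask.png")
    Image.fromarray(tile.image).save(img_path)
    Image.fromarray(tile.mask, mode="L").save(mask_path)
    return img_path, mask_path


def read_tile_pair(img_path: str) -> tuple[np.ndarray, np.ndarray]:
    mask_path = img_path[:-4] + "_mask.png"
    image = np.asarray(Image.open(img_path).convert("RGB"))
    mask = np.asarray(Image.open(mask_path))
    return image, mask


def write_ledger(nuclei: list[NucleusTruth], path: str) -> None:
    pd.DataFrame([{"x": n.x, "y": n.y, "class": n.nucleus_class.value,
                   "marker_positive": bool(n.marker_positive)}
                  for n in nuclei]).to_csv(path, index=False)


def read_ledger(path: str) -> list[NucleusTruth]:
    df = pd.read_csv(path)
    return [NucleusTruth(float(r.x), float(r.y), NucleusClass(r["class"]),
                         bool(r.marker_positive))
            for _, r in df.iterrows()]


def write_pseudo_wsi(wsi: PseudoWSI, out_dir: str, stem: str) -> dict[str, str]:
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "image": os.path.join(out_dir, f"{stem}.tiff"),
        "mask": os.path.join(out_dir, f"{stem}_mask.tiff"),
        "ledger": os.path.join(out_dir, f"{stem}_nuclei.csv"),
    }
    tifffile.imwrite(paths["image"], wsi.image, tile=(256, 256))
    tifffile.imwrite(paths["mask"], wsi.mask, tile=(256, 256))
    write_ledger(wsi.nuclei, paths["ledger"])
    return paths


def read_pseudo_wsi(out_dir: str, stem: str) -> PseudoWSI:
    image = tifffile.imread(os.path.join(out_dir, f"{stem}.tiff"))
    mask = tifffile.imread(os.path.join(out_dir, f"{stem}_mask.tiff"))
    nuclei = read_ledger(os.path.join(out_dir, f"{stem}_nuclei.csv"))
    return PseudoWSI(image=image, mask=mask, nuclei=nuclei)
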