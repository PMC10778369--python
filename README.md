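# ihcseg

Segmentation of ductal carcinoma in situ (DCIS) vs. invasive carcinoma (IC)
regions in breast-cancer IHC images, plus mask-conditioned Ki-67
quantification — testable end-to-end on procedurally generated synthetic
IHC data.

The pipeline has two training stages and a quantification stage:

1. **Stage 1** — a three-branch boundary-aware fully convolutional network
   (detail / context / boundary branches; the boundary head gates the
   fusion of the other two) trained with a combined objective (weighted CE,
   boundary BCE, boundary-aware CE) plus a confidence-gated consistency
   loss on unlabeled images (weak view pseudo-labels supervise two strong
   views and a feature-perturbed view).
2. **Stage 2** — with the backbone frozen, a two-level attentional fusion
   cascade blends three views of a large context window (reassembled corner
   crops, the direct center crop, and a 2× downscaled view) so whole-slide
   inference sees beyond tile borders.
3. **Ki-67** — H-DAB color deconvolution, watershed nucleus detection,
   positive/negative calling by DAB optical density, and index computation
   under three mask conditions (none / tumor / IC-only), with Pearson-r and
   error statistics against reference scores.

Because no public dataset ships with the package, `ihcseg.synth` generates
labeled tiles and pseudo whole-slide images with exact nucleus ledgers:
DCIS as large rounded nests with a dark continuous rim, IC as small jagged
nests, normal lobules and lymphocyte aggregates as background confounders,
and stain rendering through an optical-density forward model shared with
the deconvolution module.

There is no deep-learning framework dependency: the network, losses, and
optimizers run on a small numpy reverse-mode autodiff engine
(`ihcseg.nn`), gradient-checked in the test suite. Everything runs on one
CPU core.

## CLI

```bash
ihcseg synth --out data/ --n 200 --seed 1 --wsi      # tiles + pseudo-WSI
ihcseg train-stage1 --data data/ --out ck/ --seed 1  # backbone training
ihcseg train-stage2 --checkpoint ck/stage1_final --data data/ --out aff/
ihcseg infer --checkpoint ck/stage1_final --aff aff/aff_cascade.npz \
             --image data/pseudo_wsi.tiff --out pred/
ihcseg ki67 --image data/pseudo_wsi.tiff --mask pred/mask_level0.png --out ki67.csv
ihcseg eval --pred pred_masks/ --gt data/ --out iou.csv
```

All commands accept `--config config.yaml` (YAML mirrors the dataclasses
in `ihcseg.config`) and `--profile desk|paper`; `desk` is the CPU-scale
default, `paper` pins the published training scale (1024-px crops, 4096-px
context windows, lr 0.001, momentum 0.9, weight decay 5e-4, 300 epochs).
Each run writes its resolved config next to its artifacts. Masks export as
indexed PNG and QuPath-compatible GeoJSON.

## Layout

- `src/ihcseg/nn/` — numpy autodiff engine (tensor ops, conv, batch norm, SGD)
- `src/ihcseg/synth/` — stain forward model, tile and pseudo-WSI generators, I/O
- `src/ihcseg/network.py` — three-branch boundary-attention network
- `src/ihcseg/losses.py` — supervised losses and the consistency objective
- `src/ihcseg/augment.py`, `stage1.py` — views, feature perturbation, training
- `src/ihcseg/multiscale.py` — context geometry, AFF cascade, stage-2 training
- `src/ihcseg/wsi_inference.py` — tiling, tissue masking, stitched inference
- `src/ihcseg/ki67.py` — deconvolution, nucleus detection, index, agreement
- `src/ihcseg/evaluation.py` — IoU, stratified reporting, cross-validation
- `src/ihcseg/cli.py`, `config.py`, `geojson_io.py` — CLI, profiles, export
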