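# ductlayers

Duct-centric image features and a hierarchical evaluation protocol for
breast-biopsy ROI diagnosis from tissue-label images.

The package consumes 2D tissue-label rasters (8 tissue classes, produced
by any semantic segmenter) and computes two ROI-level descriptors:

* **Structure feature (80-dim)** — duct objects are detected as
  connected components of epithelium/secretion/necrosis superpixels;
  for each object, 5 one-superpixel-thick layers are peeled toward the
  inside and 5 toward the outside, each layer summarised by a normalized
  8-bin tissue histogram (10 layers x 8 labels). Duct histograms are
  aggregated per ROI by summing raw counts layer-wise before
  renormalizing, so the largest structures dominate.
* **Tissue distribution feature (44-dim)** — superpixel label frequency
  histogram (8 bins) plus an edge-normalized label co-occurrence
  histogram over adjacent superpixels (36 unordered pairs including the
  diagonal; a 64-bin directed variant is available behind a flag).

Features are evaluated with a three-task protocol — invasive vs
noninvasive, (atypia + DCIS) vs benign, DCIS vs atypia — using
leave-one-out cross-validation with a degree-3 polynomial-kernel SVM,
class-balanced subsampling of every training fold, PCA to 20 components
on underdetermined folds, and 100 subsampling repeats.

A synthetic-data module renders label images with category-specific
ductal morphology (thin-rim benign ducts, thick-rim atypia, filled DCIS,
rimless invasive nests in desmoplastic stroma) so the full pipeline is
testable without clinical images.

## Tissue labels

| code | name                 | palette RGB     |
|------|----------------------|-----------------|
| 0    | background           | (255, 255, 255) |
| 1    | normal_stroma        | (255, 182, 193) |
| 2    | malignant_epithelium | (178, 24, 43)   |
| 3    | blood                | (140, 0, 0)     |
| 4    | benign_epithelium    | (33, 102, 172)  |
| 5    | secretion            | (255, 255, 153) |
| 6    | desmoplastic_stroma  | (216, 179, 101) |
| 7    | necrosis             | (64, 64, 64)    |

Label images are stored as indexed PNG with exactly this palette, or as
single-channel 8-bit TIFF; both are accepted on read. ROI metadata is a
CSV manifest with columns `roi_id,label_image_path,diagnosis`
(diagnosis in benign/atypia/dcis/invasive, case-insensitive).

## Command line

```bash
# synthetic fixtures: 4 x 20 label images + manifest
ductlayers simulate --n 20 --seed 1 --out data/

# per-ROI features (structure | distribution | both)
ductlayers extract --manifest data/manifest.csv --feature structure \
    --target-area 256 --out out/

# duct objects of a single image
ductlayers ducts --image data/dcis_000.png --target-area 256 \
    --out-csv ducts.csv --out-overlay overlay.png

# three-task evaluation protocol
ductlayers evaluate --features out/features_structure.csv \
    --manifest data/manifest.csv --repeats 100 --seed 1 --out report.json

ductlayers report --report report.json
```

`--target-area` is the superpixel size in pixels (default 3000 for real
imagery; use `superpixel_px**2`, e.g. 256, for synthetic lattices). Two
superpixel backends exist: `lattice` (deterministic tiles, for
label-only input) and `color` (SLIC on a paired RGB raster).

Structure-feature CSV columns are `layer{-5..-1,+1..+5}_label{0..7}`
(rows ordered inner5 -> inner1 -> outer1 -> outer5); distribution
columns are `freq_label{0..7}` and `cooc_{a}_{b}` for `0 <= a <= b <= 7`.

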