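# ftuscope

Headless toolkit for AI-assisted annotation of **functional tissue units
(FTUs)** — glands, vessels, nerves and related structures — in H&E
histology images.

Large-scale FTU annotation is the bottleneck for structurally informed
computational pathology: outlining every gland in a whole-slide region by
hand takes hours per image. The practical remedy is a human-in-the-loop
workflow in which a segmentation model proposes annotations, a
pathologist confirms or corrects them, and the corrections feed back into
the model. `ftuscope` implements the computational core of such a
workflow as a library plus a thin CLI:

- **Controlled vocabulary** — integer class IDs ↔ FTU term names with a
  hierarchical category scheme. Ships a 17-term prostatic acinar
  adenocarcinoma vocabulary (non-tumoral glands, PIN, Gleason pattern 3,
  the GP4 subtypes cribriform / poorly formed / fused / glomeruloid, GP5
  subtypes, nerve, vascular, inflammation, artifact) and a breast
  adenocarcinoma variant (UDH, ADH, DCIS, LCIS, cribriform, solid, …).
- **Tiled inference** — plan tile windows over a large image
  (`overlapped`: 1200 px tiles at 5% overlap with nearest-center border
  resolution; `sliding`: a disjoint 1024 px grid over a reflect-padded
  canvas), run any per-tile segmentation backend, and restitch one
  seamless label mask. The trained model itself is a pluggable callable;
  reference backends (ground-truth oracle, stain-intensity threshold) are
  included.
- **Post-processing & vectorization** — fill enclosed background holes,
  drop objects under 2000 px, and trace each 8-connected component into a
  pixel-corner polygon whose re-rasterization is *exactly* the component.
- **Provenance-typed GeoJSON** — every annotation carries a UUID, class,
  metadata, a review flag and one of four provenance types (`auto`,
  `auto_checked`, `auto_edited`, `manual`); curation actions move types
  along the automation lattice. Serialization is canonical, so
  write → read → write is byte-identical.
- **Evaluation** — Dice similarity coefficient
  `DSC = 2|A∩B| / (|A|+|B|)` (class-blind for multiclass masks),
  center-pixel classification accuracy with a full confusion matrix
  (Background column = segmentation misses), Gleason-score strata
  (low ≤ 6, medium = 7, high > 7), and checkpoint comparison via
  Kruskal–Wallis plus pairwise Dunn tests with Bonferroni correction.
- **Curation efficiency** — per image, with `Am` manual-effort
  annotations (`manual` + `auto_edited`), `At` total annotations and `t`
  seconds per manual segmentation (default 10 s):
  `Pm = Am/At`, efficiency gain `1/Pm`, fully-AI fraction `1 − Pm`,
  time saved `t·(At − Am)`.
- **Synthetic tissue** — a seeded generator of H&E-like images with
  gland-style structures, matching ground-truth masks and GeoJSON, so
  every pipeline stage is testable without downloading slide data.

## Worked example

```bash
ftuscope demo --seed 1
```

simulates a 512×512 image with seven FTUs, runs tiled inference with the
ground-truth oracle backend (128 px tiles, 5% overlap), post-processes
and vectorizes the stitched mask, and evaluates it against the synthetic
ground truth. It prints:

```json
{
  "accuracy": 1.0,
  "dice": 1.0,
  "fully_ai_fraction": 1.0,
  "n_annotations": 7,
  "workdir": "/tmp/ftuscope-demo-..."
}
```

Dice 1.0 and accuracy 1.0 say the tiling, stitching, cleaning and
polygonization stages are lossless end to end — every ground-truth pixel
and every center-pixel class is recovered exactly. The same stages are
available piecewise:

```bash
ftuscope simulate --seed 5 --out-prefix work/sample
ftuscope infer --image work/sample.png --backend oracle \
    --ground-truth work/sample_mask.tif --strategy sliding \
    --tile-size 128 --out work/pred.tif
ftuscope postprocess --mask work/pred.tif --out work/pred.geojson
ftuscope evaluate --gt work/sample.geojson --pred work/pred.tif \
    --gt-mask work/sample_mask.tif --report work/report.json
ftuscope vocab-validate        # "17 terms (prostate, version 1.0)"
```

In the library, the efficiency bookkeeping at the documented worked point
(`Am=36, At=100, t=10 s`):

```python
>>> from ftuscope import efficiency_from_counts
>>> e = efficiency_from_counts("img", 36, 100, 10)
>>> round(e.efficiency_gain, 2), e.fully_ai_fraction, e.time_saved_seconds
(2.78, 0.64, 640.0)
```

## Scope

`ftuscope` deliberately excludes model training and GPU serving, viewer
integration (QuPath/napari plugins, annotation servers), and pyramidal
whole-slide I/O: backends operate on plain 8-bit RGB rasters behind the
`SegmentationBackend` seam. Real curated slide collections (e.g. the
public Miro-120 prostate dataset) can be used as input, but nothing in
the package or its tests requires a download.
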