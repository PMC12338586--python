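# Methods

This note documents the models, conventions and numerical choices behind
`ftuscope`, and what the synthetic test substrate does and does not show
about real slide data.

## Coordinate and pixel model

All geometry lives in 0-based image pixel coordinates, x rightward and y
downward, at the raster's native resolution. Pixel `(r, c)` is the
half-open unit square `[c, c+1) × [r, r+1)`; its center is
`(c+0.5, r+0.5)`. Polygon vertices sit on integer pixel corners.
GeoJSON positions are `[x, y]`. Exterior rings are stored with positive
shoelace area in the (x, y) plane, holes negative.

These conventions make polygonization exact: a pixel is inside a traced
polygon iff its center is, and centers (half-integers) never coincide
with ring vertices or axis-aligned edges (integers), so the even-odd
scanline rasterizer reproduces the traced pixel set with no epsilon.

## Polygonization of label masks

Objects are maximal 8-connected same-class components; background
topology (hole detection) is 4-connected — the standard complementary
pair that avoids both-connected paradoxes. Boundary tracing walks
directed unit edges that keep foreground on the left. At a "pinch"
corner, where two foreground pixels of a component touch only
diagonally, the walk turns through the corner so the component remains a
single ring; the ring revisits that vertex. Such rings are not
OGC-simple, but they rasterize exactly under the even-odd rule, so the
package's geometry validator accepts point-self-touching rings (repairing
them leaves the area unchanged) while rejecting true self-crossings
(repair changes the area). Hole rings become polygon interiors.

The inverse operation rasterizes arbitrary polygons by even-odd scanline
at row centers `y = r + 0.5`, filling pixels whose centers fall between
successive edge crossings. For pixel-corner polygons this is the exact
inverse of tracing; for free-hand (float-vertex) polygons it is the
deterministic pixel-center rule.

## Tiling and restitching

Two strategies cover the whole image:

- **overlapped** (default tile 1200 px, overlap fraction 0.05): stride is
  `tile − round(tile · overlap)` with round-half-to-even (1200 × 0.05 →
  60 px overlap, stride 1140). The last row/column window is clamped to
  end exactly at the image edge, so edge tiles are full-size and every
  pixel is covered.
- **sliding** (default tile 1024 px): a disjoint grid over a canvas
  reflect-padded up to a tile multiple, cropped back after stitching.
  Reflect padding means a pixel-local model sees plausible tissue rather
  than black borders; because the padded region is discarded, any
  padding-dependent predictions never reach the output.

Where overlapped windows disagree, each pixel takes the label from the
window whose center is nearest (Euclidean, on pixel centers), ties broken
by plan (row-major) order. Nearest-center ownership is deterministic,
symmetric between neighbors, and keeps tile-border artifacts away from
the label seams. Tiles are processed sequentially in row-major order;
the contract requires any parallel execution to reproduce the sequential
result bit-exactly.

The segmentation model sits behind a backend seam: a callable from an
RGB tile to a same-shape integer mask with a declared label set. Output
shape and undeclared labels are checked per tile. Two reference
backends ship with the package: a ground-truth **oracle** (crops the
known mask; the stitched result must equal it exactly, which pins down
all offset bookkeeping) and a **threshold** baseline (foreground where
mean RGB < 225, i.e. stained darker than glass; pixel-local, hence
strategy-invariant).

## Post-processing

Order of operations: fill holes, then filter small objects.

- **fill_holes** operates per component: 4-connected background regions
  unreachable from the image border without crossing that component are
  relabeled to the component's class. Nonzero pixels are never
  overwritten, so a structure nested inside another class's hole
  survives.
- **filter_small** removes components with pixel count strictly below
  `min_area` (default 2000 px, measured at mask resolution).

Both operations are idempotent, and monotone in the documented
directions (hole filling never shrinks a class; filtering never grows
one).

## Evaluation

- **Dice**: `2|A∩B| / (|A|+|B|)` on nonzero-binarized masks; the
  multiclass variant collapses every nonzero label before comparison.
  Empty-vs-empty is defined as 1.0 (perfect agreement on absence); the
  case never arises in practice but keeps the metric total.
- **Center pixel**: the pixel containing the polygon centroid,
  `(floor(cx), floor(cy))`. For non-convex shapes whose centroid falls
  outside the footprint, the fallback is the innermost footprint pixel
  by Euclidean distance transform, ties broken by smallest (row, col).
  Both rules are deterministic and always return a pixel inside the
  annotation's raster footprint.
- **Classification accuracy**: per ground-truth annotation, the predicted
  label at its center pixel; accuracy = hits / total. The confusion
  matrix is square over vocabulary classes plus Background; a Background
  prediction records a failure to segment the structure at all, which is
  tallied separately from inter-class confusion. Row normalization
  leaves all-zero rows at zero.
- **Per-image aggregation**: the headline Dice is the arithmetic mean of
  per-image scores (each image is one observation); pooled-over-pixels
  variants can be computed by concatenating masks but are not the
  default.
- **Grade strata**: Gleason score 0 encodes no tumor; 6 → low, 7 →
  medium, 8–10 → high.
- **Checkpoint comparison**: Kruskal–Wallis across groups of per-image
  Dice scores, then pairwise Dunn z-tests on pooled mid-ranks with tie
  correction, Bonferroni-adjusted over all unordered pairs
  (`p_adj = min(1, p · n_pairs)`). Dunn's test is implemented directly
  (tie-corrected rank variance `N(N+1)/12 − Σ(t³−t)/(12(N−1))`); the
  test suite cross-checks its conclusions against a 10,000-permutation
  rank-mean oracle. When every observation is identical the omnibus
  statistic is undefined; the package reports p = 1 (no evidence of
  separation).

## Curation efficiency

`Am` counts annotations that required manual segmentation effort:
provenance types `manual` and `auto_edited`. Confirmation
(`auto_checked`) is review, not segmentation, and counts as AI-generated.
With `At` total annotations and `t` seconds per manual segmentation
(default 10 s): `Pm = Am/At`, gain `= 1/Pm`, fully-AI `= 1 − Pm`, time
saved `= t(At − Am)`. Quantities are computed per image and averaged
arithmetically; per-image gains of ∞ (Am = 0) are excluded from the mean
and tallied. Because `E[1/Pm] ≠ 1/E[Pm]` (Jensen), the pooled gain
`ΣAt/ΣAm` is reported alongside the mean of per-image gains, clearly
labeled.

## Provenance model

The four annotation types record the *maximal* automation of origin:
`auto` → `auto_checked` on confirm; `auto`/`auto_checked` → `auto_edited`
on any edit; `manual` and `auto_edited` absorb further confirms and edits
unchanged. Editing a manual annotation keeps it manual — the taxonomy
describes who created the segmentation, and manual is a floor. UUIDs are
preserved under confirm/edit; only `create_manual` mints one.

## GeoJSON dialect

Package properties live under a nested `"miroscope"` object inside
Feature properties (a compatibility reader also accepts the same keys
flat). Serialization uses sorted keys, compact separators and Python's
shortest-round-trip float repr; annotations canonicalize ring
orientation at construction. Together these make serialization a fixed
point: write → read → write is byte-identical.

## Synthetic tissue generator

The generator emulates the *geometry* of gland-bearing tissue, not its
appearance: perturbed ellipses (radial modulation `1 + a·sin(kφ+φ₀)`,
a ∈ [0.03, 0.08], k ∈ 3..6) placed by rejection sampling with ≥ 2 px
clearance, so every structure is its own 8-connected component and the
returned mask, polygons and image are mutually consistent by
construction. Morphology follows the vocabulary term: single-lumen
rings for well-formed glandular classes, multi-lumen blobs for
cribriform, lumen-free nests for high-grade/solid classes, thin
elongated profiles (minor axis floor 36 px, aspect 3–4.5) for
nerve/vascular, irregular blobs otherwise. Lumens are painted in the
RGB image only; masks and polygons cover the full structure outline, as
a curator would draw it, which keeps ground truth invariant under hole
filling.

Defaults: 512×512 canvas; 7 structures over five classes (normal gland,
Gleason 3, GP4 cribriform, nerve, artifact); minor diameters 60–96 px so
every component's area clears the 2000 px post-processing threshold
(ellipse area ≥ π(d/2)²(1−ε) with ε = 0.25 covering modulation and
rasterization slack); background 243/238/242 RGB with σ = 4 Gaussian
noise. One `numpy` PCG64 stream, consumed in documented order, makes
every output byte a function of the seed.

Controlled degradation ops emulate reported failure modes: whole-object
drops (segmentation misses → Background column), erosion (boundary
under-shoot), class relabeling per a confusion specification (e.g.
high-grade patterns called Gleason 3), and sub-threshold speckle (noise
removed by area filtering).

**What passing tests do not show**: the generator contains no nuclei,
stroma texture, stain variation, tissue folds or out-of-focus regions,
and its shapes are far cleaner than real gland boundaries. Exact
recovery through the oracle pipeline validates the *plumbing* (tiling,
stitching, cleaning, vectorization, metrics) — it says nothing about the
accuracy of any real segmentation model on real tissue.

## Problem sizes

Tests and the acceptance script run on 512×512 canvases with tile sizes
64–200 px, 10,000-draw Monte-Carlo baselines and 10,000-permutation
statistical oracles — sizes chosen so the full suite completes in
seconds while still exercising multi-tile plans (up to 9×9 windows) and
every overlap/clamping branch. The tile geometry defaults (1200 px at
5%, 1024 px sliding) match production whole-slide use.

## Known limitations

- Pyramidal WSI decoding is out of scope; inputs are plain rasters.
- The GP5 subtype split needed to reach the 17-term prostate vocabulary
  is provisional (flagged in the shipped config) and user-overridable;
  the breast vocabulary covers the documented terms without claiming
  completeness.
- The compatibility GeoJSON reader accepts a flat-properties dialect on
  a best-effort basis; it is not a fidelity claim for any external
  tool's native layout.
- `efficiency_gain` is reported as ∞ when Am = 0; consumers averaging
  gains must use the provided aggregation (which excludes and tallies
  infinities) or handle them explicitly.
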