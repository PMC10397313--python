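# bordersdm

Tumor-border scanning and digitization for nanoscale spatial
transcriptomics of liver-cancer margins.

The zone where a liver tumor meets the surrounding parenchyma — the
*invasive zone*, roughly 250 µm to either side of the histological border —
concentrates much of the biology that decides recurrence: macrophage
infiltration, T-cell exhaustion, serum-amyloid-A–high (SAA⁺) damaged
hepatocytes. Studying it quantitatively requires geometry: a smooth digital
border, distance-indexed layers on both sides, and equal-area tiles along the
border so that composition can be profiled in the *normal* (perpendicular)
and *tangential* (alongside) directions. `bordersdm` implements that
scanning-and-digitization model (SDM) for Stereo-seq–style data, together
with everything around it: GEM-file binning into 25 µm pseudo-spots,
marker-score cell typing, gene-set module scores, per-layer composition
profiles, and correlation-based clustering of tangential composition
patterns with a recurrence-enrichment test.

Because the human Stereo-seq data this kind of analysis is built for are
access-controlled, the package ships a first-class synthetic slide
generator: a 10 mm × 10 mm spot grid split by a parametric border curve,
with planted, layer-dependent cell-type fractions (macrophages rising from
3.9% in the third tumor-side layer to 8.6% in the first, exhausted T cells
from 0.09% to 0.54%, total immune fraction above 30% at the border, Hep1
SAA-high hepatocytes confined to the first paratumor layer) and
negative-binomial marker-structured expression. Every pipeline stage is
validated by recovering what the generator planted.

## The model

1. **Binning** — nanoscale records (gene, x, y, count) are convolved into
   square pseudo-spots: record (x, y) → spot (⌊x/50⌋, ⌊y/50⌋), i.e. 25 µm
   (~one cell) at the 0.5 µm DNB pitch; 1000-bin (500 µm) units give local
   bulk profiles. Counts are CPM-normalized per spot.
2. **Typing** — each marker gene is z-scored across spots; a spot's panel
   score is the mean z over the panel, and the highest-scoring panel wins.
   Subtypes (exhausted T) are scored within their parent type with a
   null-noise significance gate; Hep1 vs Hep2 hepatocytes are called by the
   sign of the difference of two expression-bin-matched module scores
   (GS1 ⊃ {SAA1, SAA2} vs the complementary program GS2).
3. **Border SDM** — hepatocyte spots are rasterized (25 µm pixels),
   denoised by windowed-fraction thresholding and largest-component
   selection, the mask boundary is traced and smoothed by least-squares
   cubic splines with 20 degrees of freedom on arc length, and the curve is
   offset along its normals by ±250/500/750 µm into six layers (tumor side
   negative), plus a 250 µm "distant" reference band 2 mm out on each side.
   Each layer is cut into 100 equal-area tiles along the border; spots are
   assigned to tiles by an edge-wise cross-product (point-in-convex-piece)
   test, with a ray-casting oracle in the test suite.
4. **Profiles and patterns** — per-layer cell-type fractions under the
   "all cells" or "nonparenchymal" denominator; mean-z gene-signature scores
   per unit; and, for the invasive zone (layers ±1), bilateral tile pairs
   merged into per-position composition vectors that are clustered by
   average linkage on 1 − Pearson r, with the number of patterns chosen by
   silhouette and each pattern tested for enrichment in recurrent patients
   (log2 observed/expected score, chi-squared test).

## Worked example

```python
from bordersdm import (aggregate_bins, annotate_spots, cpm_normalize,
                       generate_slide, layer_composition)
from bordersdm.config import SlideConfig
from bordersdm.sdm import digitize_slide
from bordersdm.synth import BorderSpec, ExpressionModel

cfg = SlideConfig(slide_extent_um=(4000.0, 4000.0))
slide = generate_slide(config=cfg,
                       border=BorderSpec(amplitude_um=300.0, period_um=4000.0),
                       seed=7)
print(f"GEM records: {len(slide.gem):,}; total transcripts: {slide.gem.total_count:,}")

spots = aggregate_bins(slide.gem, 50)
cpm_normalize(spots, log1p=True)

model = ExpressionModel()
ann = annotate_spots(spots, model.panels, model.subtype_panels,
                     model.gs1, model.gs2, seed=1)
mask, curve, layers, tiles, assignment = digitize_slide(
    ann.reset_index(), slide_extent_um=cfg.slide_extent_um)
print(f"border length: {curve.length/1000:.2f} mm; tiles: {len(tiles)}")

prof = layer_composition(assignment, denominator="all", use_subtypes=True)
mac = prof[prof.cell_type == "macrophage"].set_index("layer")["fraction"]
for lab in ("-3", "-2", "-1", "+1"):
    print(f"macrophage fraction, layer {lab:>2}: {100*mac[lab]:.2f}%")
```

Output:

```
GEM records: 4,720,479; total transcripts: 51,379,613
border length: 4.16 mm; tiles: 600
macrophage fraction, layer -3: 3.89%
macrophage fraction, layer -2: 6.39%
macrophage fraction, layer -1: 8.34%
macrophage fraction, layer +1: 5.23%
```

The generator planted 3.9% / 6.0% / 8.6% / 5.0% in those layers; the whole
pipeline — expression simulation, binning, typing, border recovery, layer
assignment — reproduces the gradient within sampling error of this 4 mm
slide. Layer labels are strings: `-1` is the first 250 µm on the tumor
side, `+1` the first paratumor layer.

There is also a CLI mirroring the stages:

```bash
bordersdm full-run --out runs/demo --seed 7          # simulate → … → patterns
bordersdm simulate --out runs/demo2 --config my.yaml
```

Every run writes a `manifest.json` with parameters, seed and output hashes;
reruns with the same config are byte-identical.

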