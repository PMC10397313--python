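# Methods

This note documents the models and numerical choices behind `bordersdm`:
what each stage assumes, which defaults matter and why, what the synthetic
generator does and does not emulate, and where the design was genuinely
open. It states no result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Coordinate and unit conventions

GEM files carry integer DNB-bin indices; one bin has a physical pitch of
0.5 µm (`SlideConfig.bin_pitch_um`), origin at the slide's lower-left
corner, x rightward, y upward. All geometry downstream of file I/O is in
µm. Binning at 50 bins gives 25 µm pseudo-spots (≈ one cell); 1000 bins give
500 µm local-bulk units (~400 on a 10 mm slide). Layers are labelled
`-3…-1` (tumor side) and `+1…+3` (paratumor side), each 250 µm wide;
`distant` is the 250 µm band beginning 2 mm from the border on either side.
The border curve is oriented so the paratumor (hepatocyte) side has
positive signed distance.

## Binning and normalization

Aggregation is exact integer bucketing (`(x // b, y // b)`); empty spots are
dropped, consistent with sparse capture, and all profiling denominators use
annotated spots only. Per-spot CPM rescales each nonzero row to 10⁶. The
pipeline's default scoring layer is log1p(CPM): the negative-binomial depth
model has a heavy lower tail, and on linear CPM a single stray count in a
low-depth spot becomes a multi-sigma z-score outlier that measurably
contaminates rare-type calls; the log transform bounds that leverage. Plain
CPM remains available (`log1p=False`).

## Marker-score typing

Primary typing z-scores each marker gene across all spots on the slide (no
region restriction), averages z within each of the nine cell-type panels,
and assigns the argmax; ties break by panel order, zero-variance genes are
excluded with a warning, and a panel with no usable genes scores NaN and can
never win. This marker-score assignment replaces reference-based
deconvolution, which needs a paired single-cell reference the synthetic
data has no use for; the pipeline equally accepts an externally produced
annotation table (`read_annotation`), which is how a real SPOTlight- or
RCTD-typed slide would enter.

**Subtype gate.** Within a parent type (T/NK → conventional / exhausted),
z-scores centre on the dominant subtype, so for majority spots *every*
subtype panel scores ≈ 0 and a bare argmax degenerates to a coin flip;
conversely, spots of other primary types that leaked into the parent label
score deeply negative on the default panel, so a bare score *difference*
flags them as the rare subtype. A non-default subtype therefore requires
conjunctive evidence: its panel score must exceed `subtype_z_min`(=3)
standard errors of the null panel score (sd 1/√m for an m-gene panel), and
beat the default panel by the same multiple of the difference's null sd
(√(1/m_s + 1/m_d)). Both thresholds follow from the null model rather than
from tuning; true exhausted spots in the synthetic data score ≈ +4.7 against
a 0.95 gate, so the gate costs essentially no recall.

**Hep1/Hep2.** The module score of a gene set is mean(set) − mean(controls),
with `n_ctrl`(=100) control genes per set gene drawn (seeded) from the same
average-expression bin out of `n_bins`(=25) — depth and abundance effects
cancel, so the score is CPM-scale-free. A hepatocyte is Hep1 iff
score(GS1) − score(GS2) > 0; the threshold is fixed at zero because the two
sets are constructed as opposing programs, making the sign the natural cut.

## Border scanning and digitization

*Mask.* Hepatocyte-spot centroids are rasterized at `pixel_um`(=25 µm, one
pixel per bin50 spot). Denoising thresholds the windowed foreground
*fraction* (`window`=5 px, `keep_fraction`=0.4, edge mode "nearest"), fills
holes, and keeps the largest connected component. Thresholding the fraction
field rather than intersecting with the raw mask is deliberate: single-spot
typing makes the paratumor region ~70% speckle, and a mask that keeps the
speckle holes yields a fractal boundary that no 20-df spline can represent
(measured on a 4 mm synthetic slide: raw-contour RMS distance to the true
border ≈ 121 µm with holes vs ≈ 8 µm without). "Nearest" edge handling
prevents the filter from eroding tissue along the slide frame, which would
bend the recovered border away from the edges it should meet.

*Contour and spline.* The mask boundary is traced by marching squares,
clipped to the slide interior, and the longest interior run is kept. x(s)
and y(s) are each fit by least-squares cubic splines with `df`(=20) degrees
of freedom (df − 4 equally spaced interior knots) on the arc-length
parameter, resampled at ≤ 5 µm, and oriented so the hepatocyte side is
left/positive. A self-intersecting result raises an error advising local
segmentation — pathological borders (hairpins, parabolas opening sideways)
are out of scope and must be digitized in pieces.

*Layers and tiles.* Layer boundaries are the curve displaced along its unit
normals by 0/±250/±500/±750 µm after extending the curve's end tangents to
the slide frame (so bands close against the slide). A 20-df spline fit to a
25 µm raster contour retains genuine wiggles at the knot-spacing scale;
where their local curvature radius dips below an offset distance the
displaced polyline folds back on itself. Rather than demanding curvature
the data cannot deliver, the band between two offsets is decomposed into
≤ 5 µm normal-bounded slivers, folded quads are repaired (`make_valid`) and
overlaps deduplicated in arc order, making the decomposition an exact
partition; the band polygon is the union of its slivers and the 100 tiles
are unions of sliver runs cut at equal cumulative-area quantiles
(fractional end slivers split exactly). Consequences verified by the test
suite: tile areas sum to the band area to float precision, tile-area CV is
≈ 0 for straight borders and ≤ 10% generally, and on an analytic sinusoid
border every band point's |signed distance| lies in the nominal range
within 1%. A coarse curvature gate (measured at the 250 µm layer scale,
error above a 15% arc-fraction violation) still rejects true hairpins. The
distant bands are built by two-sided buffering split by side, which prunes
self-intersections at the 2 mm offset where even gentle borders violate the
curvature bound.

*Assignment.* Tiles are decomposed into convex (triangle) pieces and a spot
is inside iff the cross products of each edge with the spot share a sign
over some piece; boundary spots go to the lowest (layer, tile) index, and
spots in no tile are labelled `distant` or `none` by signed distance. A
signed-distance field and an even-odd ray-casting test serve as independent
oracles in the tests, never as the primary path.

## Zone profiles

Layer composition is reported under both denominators the field uses —
"all cells" and "nonparenchymal" (malignant/cholangiocyte and hepatocyte
excluded) — because figures alternate between them; the acceptance targets
use "all cells". With `use_subtypes=True` a spot with a subtype call counts
as its subtype and the parent keeps the remainder, so fractions never
double-count. `gradient_summary` reports across-slide means ± sd with plain
two-sample t-tests between adjacent layers (reporting plumbing, not a novel
statistic). The per-unit `signature_score` is the mean z-score of a gene
set across units — an intentionally simple directional summary standing in
for pathway-level scoring (GSVA-class methods are external tools and out of
scope); it is used only for direction-of-effect checks.

## Tangential patterns

Counts of the seven nonparenchymal types in the two bilateral first-layer
tiles at the same tangential position are merged and normalized. When tile
geometry is available the merge uses common cut positions (the per-cut mean
of the two layers' arc positions): equal-area cuts of the inner and outer
band shift against each other by up to a tile width where the border bends
(mean ≈ 0.7 tile widths on the default sinusoid), and index-based pairing
would smear pattern boundaries. Distance is 1 − Pearson r, linkage is
average, and for `k="auto"` every tree cut in 2…10 is evaluated after
folding clusters below 1% of vectors into the nearest major centroid —
average linkage detaches far outliers before it splits genuinely adjacent
patterns, so a raw cut counts outliers rather than patterns; the cut
maximizing the mean silhouette of the folded labelling wins. Patterns are
renumbered by decreasing size; zero-variance vectors cannot enter a
correlation and are assigned to the nearest centroid afterwards, flagged.
The recurrence enrichment score of a pattern is log2 of its recurrent-vector
fraction over the overall recurrent fraction — a declared reconstruction,
since no algebraic definition exists to follow — with one chi-squared test
on the K × 2 pattern-by-recurrence table. The chi-squared p-value treats
tiles as independent; with spatially contiguous archetype runs it is
anti-conservative, which is acceptable for the planted, strongly enriched
alternative but matters under the null (the null test in the suite uses
independent per-tile draws).

## The synthetic generator

The generator emulates exactly the statistical structure the analysis
consumes, at the study's stated conditions: a 10 mm × 10 mm slide of
160,000 bin50 spots (one spot ≈ one cell, no doublets), a sinusoidal border
(amplitude 400 µm, period 5 mm — curvature radius ≈ 1.6 mm, comfortably
offsettable), and per-layer type fractions planting the published gradients:
macrophages 3.9/6.0/8.6% in layers −3/−2/−1, exhausted T cells
0.09/0.30/0.54%, immune total 32% in layer −1, Hep1 = 60% of layer +1
hepatocytes and absent elsewhere. Other types' layer gradients are free
parameters chosen once to be qualitatively consistent (hepatocytes dominate
the paratumor side and rise away from the border; malignant cells mirror
that on the tumor side).

*Exact-margin planting.* Within each truth region, spot types are a random
permutation of a deterministic count vector (largest-remainder rounding of
the planted fractions) rather than iid draws. The generator exists for
ground-truth recovery: with exact margins, any discrepancy in a recovered
fraction is attributable to the pipeline, whereas iid sampling noise alone
(sd ≈ 0.12 percentage points for the 0.54% exhausted-T fraction at ≈ 4,100
spots/layer) would be of the same order as the recovery tolerances.

*Expression.* Counts are gamma-mixed Poisson (negative binomial): per-spot
depth ~ Gamma(1/α, mα) with m = 2000 (inside the 589–4642 molecules/spot
range such data show) and dispersion α = 0.5, distributed over 240 genes
proportional to a per-class weight vector: a fixed log-normal baseline
(σ = 1.5) with the class's 10 markers up-weighted 2³-fold (SAA1/SAA2
2⁴-fold in Hep1; subtype and hepatocyte-program panels analogous). Marker
and program genes have their baseline floored at the transcriptome median —
curated marker panels are detectable genes by construction, and tail-
baseline "markers" are pure shot noise in the very cells that express them.
The 240-gene transcriptome is a deliberate scale-down: it preserves the
marker-vs-background contrast the methods act on while keeping a full slide
around 30 M GEM records.

*Cohort.* 16 patients (half recurrent), one slide each, borders phase-
shifted. The invasive zone's nonparenchymal composition follows one of five
archetypes per contiguous tangential run (geometric run length, mean 25
tiles — patterns occur in large contiguous blocks). Archetype dominance is
deliberately strong (e.g. fibroblast 0.70 in pattern 1, macrophage 0.72 in
pattern 3): a multinomial identifiability check showed that with the ~20–40
nonparenchymal cells a merged tile pair yields, softly dominant archetypes
are not mutually distinguishable by *any* composition clustering — the five
planted patterns must be separable for recovery to be a meaningful test.
Recurrent patients' mixtures multiply pattern 3's odds by 3 and pattern 1's
by 1/3. Cohort slides are generated annotation-only by default, since the
pattern analysis consumes annotations; expression can be switched on.

*What the generator does not emulate* — and what passing tests therefore do
not show about real tissue: transcriptome-wide gene–gene covariance,
segmentation-free cell morphology, doublets and partial cells at bin50,
spatial autocorrelation of expression within a cell type, multifocal or
capsule borders, and batch/section effects. Recovery results demonstrate
that the pipeline's geometry and estimators are correct, not that typing at
these accuracies is attainable on real Stereo-seq slides.

## Problem sizes and determinism

Default analyses run on one 160k-spot slide (≈ 30 M GEM records, ≈ 5 GB
peak, ~1.5 min end to end) and a 16-slide annotation-only cohort (~1 min);
the test suite exercises the same code mostly at 1.5–4 mm slide scale. All
randomness flows through explicit seeds (`numpy.random.default_rng`); the
CLI derives per-stage streams from one run seed by fixed offsets, and a
rerun with the same config is byte-identical (hashes in `manifest.json`).
Known limitations: single-component borders only; the 20-df spline is not
scale-aware (very small slides put knots so close together that raster
noise folds the outer offsets — handled by the sliver dedup, but border
accuracy degrades); silhouette-based k selection remains heuristic and is
reported alongside the full silhouette-by-k table.
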