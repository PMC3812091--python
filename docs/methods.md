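# Methods

## The assay and what the pipeline measures

In a 96-well feeding-RNAi screen, adult *C. elegans* are imaged per well in
brightfield plus one fluorescence channel (Nile red fed as a vital dye marks
lysosome-related organelles, LROs; DAPI/GFP filter sets capture intestinal
autofluorescence; fixative Nile red marks neutral lipid droplets).  The
pipeline turns each well into a single number — by default the
background-adjusted 90th-percentile fluorescence intensity of the worm
pixels — and then treats the per-well numbers as a replicate screen table
for hit calling and clustering.

Raw images carry 12-bit data in 16-bit TIFF containers.  The declared bit
depth is metadata only: pixels are stored as read and rescaled explicitly
where an 8-bit representation is needed.

## Well finding

The tiled brightfield image is blurred with a 30×30 Gaussian (σ = 30/6 = 5;
the kernel size is a published parameter, the σ convention is ours),
converted to 8 bit over its declared dynamic range, and thresholded at
`L·F`, where `L` is the Otsu level of the 256-bin histogram and `F = 0.9`
biases the cut against false-positive well pixels.  Holes are filled
(4-connected background), the largest 8-connected component is kept, and
the mask is eroded with a 30 px diameter disk.  A 30 px false border is
padded on before the erosion and removed afterwards, which makes the result
identical to eroding the infinitely zero-padded mask — wells truncated by
the image edge keep their interior instead of losing a rim to boundary
effects.  A well covering more than half the frame is flagged suspicious
but still returned (the bound is this package's sanity check, not part of
the published procedure).

## Object finding

Within the well, three exclusive masks are produced — objects (worms), junk
(eggs, debris: real foreground that must not be quantified), and
background — whose union is exactly the well mask.  The cascade:

1. **Bottom-hat** with a 20 px diameter disk (grayscale closing minus the
   image): dark worms become bright peaks on a flattened background.  The
   disk is the set of pixels within Euclidean distance D/2 of the center.
2. **Saturate and quantize**: the (1−0.01) quantile maps to 255 and the
   minimum to 0 (1% of pixels clip); quantization truncates to 8 bits.
3. **Otsu with effectiveness** on the well pixels only: exhaustive search
   over the 255 cuts of the 256-bin histogram; ties break to the lowest
   cut.  The effectiveness `E` is the maximized between-class variance
   divided by the total variance — 1 for a cleanly bimodal histogram,
   near 0 for a featureless one.
4. **Threshold method** (when `L ≥ 0.05` and `E ≥ 0.7`): foreground are
   well pixels strictly above `round((1 − F·(1−L))·255)` with `F = 0.9`,
   followed by a 3 px disk closure to remove pinholes.
5. **Outlier method** (when `L` or `E` is inadequate): the *un-quantized*
   bottom-hat image is blurred with a 3×3 Gaussian and pixels beyond
   `Q3 + 3·IQR` of the well pixels (type-7 quartiles) are foreground.  For
   normal background this cut sits `7·Φ⁻¹(0.75) ≈ 4.72σ` above the mean.
   Two design points here were forced by degenerate-input analysis and are
   deliberate departures from the more obvious wiring:
   - the outlier mask *replaces* the threshold mask rather than OR-ing
     into it.  When the Otsu level is inadequate the threshold mask is
     garbage (in a noise-dominated well it covers ~85% of the area), and
     a union would both bury real small objects and permanently disable
     the small-object path below;
   - the whisker cut is taken on raw bottom-hat intensities, not the
     saturation-stretched 8-bit image.  After a 1%-saturation stretch of a
     noise-dominated well the background occupies the full 8-bit range and
     `Q3 + 3·IQR` lands above 255, so the method could never fire there;
     on raw intensities the background is approximately normal and the
     4.7σ interpretation holds.
   The outlier detection is one-sided (high tail) because bottom-hat
   foreground is bright; a config flag enables two-sided.
6. **Size filtering**: 8-connected components with area inside the limits
   become objects; components that passed thresholding but fail the size
   filter become junk; everything else in the well is background.  If the
   largest component is smaller than the small-region trigger, the
   small-object limits are applied instead.  Defaults (unpublished,
   config-exposed, chosen for the phantom scale): threshold
   [100, 50000] px, outlier [30, 50000] px, small-object [15, 2000] px,
   trigger 300 px.

QC flags (`low_effectiveness`, `low_level`, `low_object_count` below 1
object, `high_junk_ratio` above 5× junk-to-object area) all imply
`manual_review`; a zero-variance well returns an all-background, fully
flagged result rather than an error.

## Quantification

Per mask: intensity histogram at native resolution (4096 bins for 12-bit
data), mean, median and the 90th percentile (type-7 linear interpolation;
medians of even counts use the midpoint, consistent with type 7).  Because
the background distribution is approximately normal with small σ, adjusted
estimates subtract the background mean from the object and junk statistics.
Adjusted values may be negative (dim objects over bright background); they
are reported unclipped with a flag so that downstream fold changes remain
linear.  Empty masks produce missing values, never zeros.

## Screen statistics

**Hit calling.**  Each gene's replicate values are compared against the
pooled vector-control replicates of the same strain with Welch's
unequal-variance two-tailed t-test; p-values are corrected across all genes
tested in that strain.  Plain Bonferroni is the default (the stringent
cutoff); Holm's step-down is provided as the uniformly-no-less-powerful
alternative and `p_holm ≤ p_bonferroni` always.  Fold change is the ratio
of arithmetic means of the raw adjusted-p90 values; a flag switches the
test (not the fold change) to log2 values, where multiplicative noise is
exactly normal.  Degenerate variance is handled by convention: two constant
equal groups give p = 1, constant separated groups give p = 0.

**Power at this design.**  At the screen's design point (6 vs 6
replicates, Bonferroni over 571 genes) the noncentral-t power for an effect
of 3 noise-SDs is 29.3% (ncp = 5.20, df = 10, t_crit = 6.31); 90% power
requires a ≈4.84-SD effect.  The acceptance script reports both the
empirical recovery and this prediction.  Because every gene in a strain
shares one control sample, per-screen power is strongly correlated across
genes: single screens tend to recover either most detectable hits or
almost none, and only the average over many screens approaches the
noncentral-t value.

**Normalization and clustering.**  Gene × strain matrices are log2
transformed and quantile normalized (rank-wise column means; ties within a
column receive the mean of their ranks' reference values), so every column
shares one reference distribution.  k-means (k-means++ initialization, 50
restarts per k, tolerance 1e-8, seeded) is run over k = 1..15 and the best
within-cluster total sum of squares (wss) is kept per k.  The cluster
number is the first strict local minimum of wss(k); when the curve is
monotone — the usual case for best-of-restarts — the elbow (largest second
difference) is used and the result is flagged.  Columns are ordered by
complete-linkage hierarchical clustering of Euclidean column profiles, and
cluster separation is summarized by the first two principal components.
Heatmap display uses per-column z-scores, which show direction of effect
per background but not absolute magnitude.

**qPCR.**  Relative expression uses the efficiency-corrected ΔΔCt form
`fold = E_t^(ΔCt_t) / E_r^(ΔCt_r)` with experimentally determined per-cycle
efficiencies in (1, 2.2].

## Synthetic data

**Phantom wells** emulate the imaging geometry at a reduced scale chosen to
keep the full test suite fast: a 360×360 px frame, a 160 px radius bright
well (12-bit background N(2800, 60) plus a ±150-count linear illumination
gradient) on a dark surround; worms as smoothed random-walk spines dilated
to 5–9 px wide tubes, 60–120 px long, at 0.45× background in brightfield;
eggs as 2–5 px ellipses and debris as 10–60 px irregular blobs at 0.6×
background.  The paired fluorescence channel draws worms at mean 3400 over
the same background, so the planted object/background contrast is 600
counts.  Eggs and debris are placed clear of worms so the truth labels
stay unambiguous under 8-connectivity.  The phantoms exercise every code
path (threshold, outlier, small-object) but are deliberately simple: no
PSF, vignetting, motion blur, worm overlap with junk, or texture inside
worms — a pixelwise F1 of ~0.99 on phantoms therefore bounds nothing about
real images beyond the pipeline's logical correctness.

**Screen tables** follow `value = baseline · fold · exp(N(0, sd²))` with
fold 1 for controls, 571 genes × 6 replicates by default and noise sd 0.2
on the natural-log scale (≈20% well-to-well CV, a realistic figure for
whole-well intensity assays).

**Clustered profiles** plant k centroids that are near-equidistant
(repulsion on a sphere, rescaled so the minimum pairwise distance equals
the requested separation) with balanced cluster sizes and isotropic noise.
Near-equidistance matters: for a regular simplex the between-centroid sum
of squares is linear in the number of clusters, so the wss curve breaks
sharply at the planted k; loosely scattered centroids hide the break under
large-scale structure and no selection rule could recover k reliably.

All generators are pure functions of (spec, seed).

## Numerical conventions

- Coordinates are (row, col), 0-based, origin top-left, everywhere.
- 8-bit conversion rounds half away from zero; saturation-quantization
  truncates (so exactly the clipped fraction maps to 255).
- Threshold comparisons are strictly greater-than in 8-bit units.
- Disk structuring elements: pixels with Euclidean distance ≤ D/2.
- Quartiles and percentiles are type 7 (linear interpolation) throughout.
- Otsu ties break to the lowest level; all clustering randomness flows
  from an explicit master seed; image segmentation is fully deterministic.

## Known limitations

- No per-worm statistics, worm untangling, or tracking; touching worms are
  quantified as one object.
- No plate-effect or mixed-effects modelling; control pooling assumes a
  homogeneous assay batch per strain.
- The elbow rule is only identifiable when cluster scales are comparable;
  strongly hierarchical structure will elbow early, and the flagged
  no-local-minimum state should be inspected rather than trusted blindly.
- The whisker-σ equivalence and the Welch far-tail calibration both assume
  approximately normal background/noise; heavy-tailed noise would make the
  outlier method over-segment and uncorrected p-values anti-conservative.
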