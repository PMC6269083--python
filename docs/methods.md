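# Methods

This note documents the models implemented in slidescope, the defaults and
why they were chosen, what the synthetic generator does and does not emulate,
and the numerical choices that affect results.

## Acquisition geometry

Tiles are laid out on a regular grid with origin spacing
`round(index * tile_size * (1 − overlap))` pixels; the serpentine acquisition
index maps to `(row, col)` with odd rows reversed. Coordinates are 0-based,
rectangles half-open, y increases downward — the raster convention, chosen so
that the *unique regions* (each tile's exclusively-owned span, ending at the
next tile's origin, extended to the full tile on the last row/column) tile
the slide exactly once with no fractional-pixel bookkeeping.

The default pixel size, 0.54 µm/px, is inferred from a ~1.4 mm camera field
of view on a 2592-px-wide sensor. It is an inference, not a calibration, and
every entry point accepts an override; all physical quantities (areas,
densities, kernel sizes) scale with its square.

## Flat-field correction

`I_corr = 255 (I − I_bg)/(I_bf − I_bg)` is applied per RGB channel, clamped
to [0, 255] and rounded half-up (half-up rather than banker's rounding for
bit-reproducibility across platforms). Whether the original method applied
the formula per channel or on luminance is not documented anywhere we know
of; per-channel is the natural reading for color work and is what the
deconvolution stage needs. Pixels brighter than the brightfield (specular
highlights) are clamped, not errors. Validation requires
`I_bf − I_bg ≥ 1` grey level everywhere; an optional median smoothing of the
calibration pair (off by default) suppresses dust specks.

## Stain separation

Optical density uses a +1 offset, `OD = −ln((I+1)/256)`, so that 8-bit black
stays finite (OD ≈ 5.545) and white is exactly 0. Concentrations solve
`OD = c · M` per pixel with negative solutions clamped to zero. The H&E
matrix uses the published Ruifrok–Johnston haematoxylin/eosin vectors with a
cross-product residual row. **No canonical LFB/NFR vectors exist**; the
built-in matrix is an estimate (a blue stain absorbing red > green, a red
stain absorbing green > blue) that should be replaced by a slide-specific
calibration for real material. The synthetic generator composes images with
the exact configured vectors, so generator–analysis consistency holds by
construction.

Downstream statistics use *density* channels (high = more stain), not
transmission: myelin weighting in the fiber stage only makes sense as a
positive quantity. The relative-intensity measure `I_rel` is therefore the
LFB share of summed densities; this is an interpretation choice, documented
here rather than prescribed by any source.

Information limit: at high total OD the 8-bit composite saturates toward
black and the per-channel OD uncertainty `~0.5/(I+1)` grows without bound,
so deconvolution accuracy at densities ≳2 under strongly absorbing vectors
is physics-limited, not implementation-limited. The round-trip validation
(`< 0.05` per channel over concentrations in [0, 2]³) therefore uses an
orthonormal stain basis, which keeps every composite channel ≥ 33 grey
levels and isolates the algebra and quantization handling; a float-precision
check with the real H&E vectors covers the realistic operating range.

## Nuclei segmentation

Stage order is fixed: Phansalkar threshold → size filter → watershed →
channel refinement → size filter → morphometry.

* **Phansalkar threshold** `T = m(1 + p e^{−qm} + k(s/R − 1))` with the
  method's published constants p=2, q=10, k=0.25, R=0.5; window radius 15 px
  (~16 µm at the default pixel size, i.e. about two nucleus diameters);
  reflective boundary handling. Input is the nuclear density channel divided
  by `density_norm` (default 2.0 — a darkly stained nucleus has density ≈ 1,
  mapping to 0.5).
* **Size filter** retains components with area in [10, 2500) µm². The upper
  bound is the pipeline's defining retention rule; the 10 µm² lower bound
  suppresses speckle and is our addition. The filter runs both before the
  watershed (on clusters) and after refinement (on split nuclei), because
  the retention rule speaks of "nuclei or clusters thereof".
* **Watershed** on the negated Euclidean distance transform. Seeds are local
  maxima of the EDT, lightly Gaussian-smoothed (σ = 1 px) to avoid plateau
  oversplitting of elongated nuclei, separated by ≥ 7 px (about one nucleus
  diameter), ordered by (y, x) for determinism; components without a peak
  keep their EDT argmax as a single seed. Ridge pixels are assigned to
  background, so splitting changes foreground only by the ridges.
* **Channel refinement** removes labels whose per-channel mean density
  violates configured bounds; default: haematoxylin mean ≥ 0.15, other
  channels unbounded. The bound was calibrated on the synthetic fixtures
  (it cleanly separates rendered nuclei, mean ≈ 1, from eosin-only mimics,
  mean ≈ 0) and is exposed in config — for real slides it must be re-tuned.
  Refinement runs after the watershed, following the stage order above.
* **Morphometry** via second-moment ellipse properties: centroid (converted
  to slide micrometers through the tile origin), pixel-count area,
  eccentricity. Detections whose centroid falls outside the tile's unique
  region are discarded.

**Overlap deduplication.** The centroid-in-unique-region rule alone double
counts a nucleus whose pixel support straddles a unique-region boundary: the
owning tile reports it in full, and the neighbour sees a clipped fragment
whose own centroid lies inside the neighbour's unique region. A record-level
merge therefore follows: detections from *different* source tiles closer
than `dedup_radius_um` (default 4 µm, about one nucleus radius) are treated
as one nucleus and the larger-area record wins. On synthetic slides (one
globally rendered scene cut into tiles, so overlap pixels are identical)
this recovers every true nucleus exactly once; on real slides it assumes the
stage positioning error is small against the nucleus radius.

## Heatmaps

Non-overlapping square kernels, default 500 µm, half-open membership by
centroid; per kernel the count, cellularity (count / true kernel area, with
boundary-clipped kernels using their clipped area), and mean / population SD
/ COV of area and eccentricity. Empty kernels are *undefined* (NaN), not
zero: measured zero cellularity and absent tissue are different things.
Kernel counts sum to the number of input records exactly, for any kernel
size. Regional summaries aggregate kernels whose centers fall in the region
(mask, polygon or predicate) and report mean, population SD, median and IQR
with linear-interpolation (type-7) quantiles — stated because IQR values
depend on the quantile rule. Summaries are kernel-level, matching the
per-mm² units of cellularity, rather than pooled per-nucleus statistics.

## Fiber orientation

Sobel gradients (kernels normalized so a unit ramp gives unit magnitude) on
the LFB density channel; orientation is direction folded modulo 180°
*before* density estimation — gradient sign carries no orientation
information, and fitting raw directions instead would split each
orientation's mass into two antipodal lobes (an `fold_angles=False` escape
hatch reproduces that behaviour on (−180°, 180°]). The orientation density
is a wrapped Gaussian KDE: fixed bandwidth 5°, evaluation grid 1°, samples
replicated at ±period. The mode's perpendicular is the fiber orientation;
`M_rel` uses the grid maximum and minimum (grid, not continuous, minimum —
stated because the two differ slightly). The KDE is unweighted by default;
`kde_weighted=True` weights samples by gradient magnitude.

Subtiles are 64 px squares (≈ 35 µm at default pixel size; partial edge
subtiles participate). Pixels whose residual-channel density exceeds 1.0 are
excluded as impurities (dust and pigment load the residual channel; the
threshold is a synthetic-fixture calibration, exposed in config). A subtile
is invalid when fewer than half its pixels survive, or its mean gradient
magnitude over valid pixels falls below 0.01 density units/px — a blank
field has zero gradient and must not report an orientation. "Absolute
magnitude" in the HSV value product is the subtile mean of the gradient
magnitude over valid pixels. Display normalization clips the value/weight
products at their 99th percentile over valid subtiles. With y pointing down,
θ = 90° means fibers running top-to-bottom on screen.

## Synthetic generator

What it emulates: elliptical haematoxylin-dense nuclei (area ~
N(40, 8²) µm², eccentricity uniform in [0.2, 0.7] — glial/neuronal nuclei of
~7 µm diameter), placed by Poisson sampling with non-overlap rejection on a
uniform eosin background; Beer–Lambert composition with the configured stain
vectors; additive Gaussian camera noise (SD 3 grey levels); sinusoidal LFB
gratings (period 16 px, contrast 0.25 density units) at known orientations;
multi-region scenes (the demo uses cortex / white matter / tumor bands at
2473 / 3581 / 5714 nuclei/mm², the measured magnitudes of those tissue
classes); per-tile vignetting as a radial quadratic gain in [0.7, 1] times
an exposure scale, plus a constant sensor offset of 5 grey levels, with the
matching float-valued calibration pair (the exposure scale keeps the
brightfield just below saturation, as a real acquisition would).

Ground truth is analytic — placed centers, π·a·b areas, closed-form
eccentricities — never re-measured from the rendered raster. Nuclei are kept
fully inside the scene so the analytic truth is exact. All generators are
byte-deterministic under a fixed seed.

What it does **not** emulate, and hence what passing tests do not show:
chromatin texture and staining heterogeneity within nuclei, overlapping
(truly stacked) nuclei, out-of-focus blur, stage positioning error between
tiles, stain-vector drift across a slide, tissue folds/tears, and realistic
white-matter texture beyond a single-frequency grating. Detection scores on
the synthetic fixtures are therefore upper bounds on real-slide performance;
the fixtures validate the algorithms' correctness, not clinical accuracy.

## Problem sizes used in validation

Validation runs use sizes chosen to exercise every code path at desk scale:
a 1 mm² single tile at 3000 nuclei/mm² for detection scoring; a 3 × 3 mm
three-band slide (2 × 2 grid of 2926-px tiles, 5% overlap, ~37 000 nuclei)
for regional cellularity recovery; 512-px gratings at eight orientations for
fiber recovery; and a small 2 × 2 vignetted slide for restoration,
deduplication and determinism checks.

## Known limitations

* Tile positions are trusted from the grid geometry; there is no
  cross-correlation stitching refinement, and a downsampled overview PNG
  stands in for a multi-resolution pyramid.
* The LFB/NFR stain vectors and the refinement/impurity thresholds are
  fixture-calibrated defaults, not measured constants.
* The watershed separates moderately touching nuclei but not heavily
  overlapping ones; there is no learning-based segmentation.
* Orientation is per-subtile and in-plane only; no streamline integration
  across subtiles.
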