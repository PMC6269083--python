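# slidescope

Tile-based analysis of oversized histology slides: flat-field illumination
correction, stain separation by color deconvolution, nuclei segmentation with
cellularity/morphometry heatmaps, and gradient-based fiber-orientation mapping
— plus a ground-truthed synthetic slide generator so the whole pipeline can be
validated end to end without glass.

## Who this is for

Labs that digitise large-format slides (e.g. whole human brain sections) as a
grid of overlapping camera fields of view on a custom scanning stage, and then
want quantitative maps rather than just a stitched picture: where is
cellularity elevated (tumor infiltration), how do nuclear size and shape vary
across regions, and how are myelinated fiber tracts oriented in LFB-stained
white matter.

## The processing model

**Acquisition geometry.** A slide is an `n_rows x n_cols` grid of 8-bit RGB
tiles with a known overlap fraction (typically ~5%), acquired serpentine-wise.
Tile origins are trusted from the stage geometry; each tile owns a half-open
*unique region* and the unique regions partition the slide exactly, which
makes mosaic composition and detection deduplication well defined.

**Flat-field correction.** Without Koehler illumination each tile carries a
smooth vignetting gain and a sensor offset. Both are measured once with a
brightfield and a background calibration exposure, and every tile is corrected
per pixel and channel:

    I_corrected = 255 * (I_original − I_background) / (I_brightfield − I_background)

**Stain separation.** Absorbing stains add in optical density
`OD_c = −ln((I_c + 1)/256)`; per-pixel concentrations follow by inverting the
3x3 stain matrix (Ruifrok–Johnston vectors for H&E; a documented estimate for
LFB/NFR). Downstream analysis works on density channels (high = more stain).

**Nuclei.** On the haematoxylin density channel:
Phansalkar local thresholding `T = m(1 + p e^{−qm} + k(s/R − 1))` →
size filtering (objects < 2500 µm² retained) → distance-transform watershed to
split touching nuclei → per-channel mean-density refinement (rejects
haematoxylin-poor objects such as corpora amylacea) → centroid/area/
eccentricity morphometry. Records are binned into square evaluation kernels
to map cellularity (nuclei/mm²) and the mean/SD/COV of area and eccentricity.

**Fibers.** On the LFB density channel, per square subtile: Sobel gradient
orientations (folded to [0°, 180°)) are pooled into a wrapped Gaussian-kernel
density `P`; the dominant fiber orientation is perpendicular to the density
mode, `θ = (argmax P + 90°) mod 180°`, with
`M_rel = max P / (max P + min P)` (0.5 = isotropic, → 1 = strongly oriented)
and `I_rel = 3·ΣI_LFB / ΣI_total` (myelin share of total stain). Maps are
rendered as HSV (hue = orientation) and as a red/green horizontal/vertical
projection.

## Worked example

```python
import numpy as np
import slidescope as s

# synthetic H&E tile, ~0.55 x 0.55 mm at 0.54 um/px, with exact ground truth
rgb, truth = s.render_nuclei_tile((1024, 1024), 0.54, nuclei_per_mm2=3000.0, seed=42)
grid = s.TileGrid(1, 1, 1024, 1024, overlap=0.0, pixel_size_um=0.54)
records = s.segment_tile(s.deconvolve(rgb, s.he_matrix()), grid, 0, 0)
print(f"true nuclei: {len(truth)}   detected: {len(records)}")

hm = s.build_heatmaps(records, grid.slide_extent_um, kernel_size_um=250.0)
summ = s.region_summary(hm, lambda x, y: True)
print(f"cellularity over {summ['n_kernels']} kernels: mean {summ['mean']:.0f} /mm^2, "
      f"sd {summ['sd']:.0f}, median {summ['median']:.0f}, IQR {summ['iqr']:.0f}")

# synthetic myelin grating at 30 degrees
tile = s.render_fiber_tile(30.0, size_px=(512, 512), seed=7)
results = s.analyze_slide(tile, s.lfb_nfr_matrix(), s.FiberParams(), 0.54)
valid = [r for r in results if r.valid]
print(f"fiber subtiles: {len(valid)}/{len(results)} valid, "
      f"median theta {np.median([r.theta_deg for r in valid]):.1f} deg")
```

prints

```
true nuclei: 943   detected: 943
cellularity over 9 kernels: mean 3018 /mm^2, sd 153, median 3072, IQR 300
fiber subtiles: 64/64 valid, median theta 30.0 deg
```

All 943 generated nuclei are recovered; the kernel-wise cellularity mean
(3018/mm²) matches the generator density (3000/mm²) to within Poisson
sampling noise, and the fiber analysis recovers the 30° grating orientation
in every subtile.

The same stages are available from the shell:

```sh
slidescope synth --out demo/slide --seed 2          # tiles + manifest + truth
slidescope correct --brightfield demo/slide/brightfield.tif \
    --background demo/slide/background.tif --in demo/slide/tiles --out demo/corr
slidescope segment --manifest demo/slide --out demo/nuclei.csv
slidescope heatmap --nuclei demo/nuclei.csv --extent-um 421 421 --out demo/hm
slidescope run --out demo/full --seed 3             # everything, one command
```

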