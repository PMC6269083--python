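"""Ground-truthed synthetic slide generator.

Emulates the two slide types the analysis pipeline consumes:

* H&E-like tissue — elliptical hematoxylin-dense nuclei placed without
  overlap on a uniform eosin background, composed to RGB via Beer–Lambert
  absorption with the configured stain vectors, plus Gaussian camera
  noise.  Ground truth (centroids, areas, eccentricities) is analytic,
  never re-measured from the rendered raster.
* LFB/NFR-like white matter — a sinusoidal grating of LFB density at a
  known orientation on a constant nuclear-fast-red background.

Whole synthetic slides sample one global scene (multiple regions of
differing nuclear density and/or fiber orientation), then cut it into
overlapping camera tiles per a :class:`~slidescope.geometry.TileGrid`,
optionally applying a per-tile vignette (radial quadratic gain in
[1-strength, 1] times the scene, plus a constant sensor offset) together
with the matching brightfield/background calibration pair, so that
flat-field correction and overlap deduplication are exercised end to end.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import ParameterError, SlidescopeError
from .geometry import TileGrid
from .records import NucleusRecord, ellipse_eccentricity, write_manifest
from .stains import StainMatrix, he_matrix, lfb_nfr_matrix

# default nuclear morphometry: glial/neuronal nuclei of ~7 um diameter
DEFAULT_AREA_UM2_MEAN = 40.0
DEFAULT_AREA_UM2_SD = 8.0
DEFAULT_ECC_RANGE = (0.2, 0.7)


@dataclass(frozen=True)
class RegionSpec:
    """One scene region: a geometry plus tissue parameters.

    ``shape`` is ``("all",)``, ``("rect", x0, y0, x1, y1)`` or
    ``("disc", cx, cy, r)`` in micrometers.  Later regions sit on top of
    earlier ones.  ``fiber_orientation_deg`` of None means no oriented
    texture; ``fiber_contrast`` 0 gives a texture-free LFB level.
    """

    shape: tuple
    nuclei_per_mm2: float = 0.0
    area_um2_mean: float = DEFAULT_AREA_UM2_MEAN
    area_um2_sd: float = DEFAULT_AREA_UM2_SD
    ecc_range: tuple[float, float] = DEFAULT_ECC_RANGE
    fiber_orientation_deg: float | None = None
    fiber_period_px: float = 16.0
    fiber_contrast: float = 0.25
    name: str = ""

    def mask_px(self, shape_px: tuple[int, int], pixel_size_um: float) -> np.ndarray:
        h, w = shape_px
        kind = self.shape[0]
        if kind == "all":
            return np.ones((h, w), dtype=bool)
        # broadcast 1-D coordinate vectors; full 2-D grids are never built
        x_um = ((np.arange(w, dtype=np.float32) + 0.5) * pixel_size_um)[None, :]
        y_um = ((np.arange(h, dtype=np.float32) + 0.5) * pixel_size_um)[:, None]
        if kind == "rect":
            _, x0, y0, x1, y1 = self.shape
            return ((x_um >= x0) & (x_um < x1)) & ((y_um >= y0) & (y_um < y1))
        if kind == "disc":
            _, cx, cy, r = self.shape
            return (x_um - cx) ** 2 + (y_um - cy) ** 2 < r * r
        raise ParameterError(f"unknown region shape {kind!r}")


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic slide scene."""

    regions: tuple[RegionSpec, ...]
    stain: str = "HE"  # "HE" or "LFB-NFR"
    nucleus_stain_density: float = 1.0
    background_density: float = 0.35  # eosin (HE) / NFR (LFB-NFR) level
    lfb_base: float = 0.6
    noise_sd: float = 3.0  # grey levels
    vignette_strength: float = 0.3
    vignette_offset: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if any(r.nuclei_per_mm2 < 0 for r in self.regions):
            raise ParameterError("nuclei densities must be >= 0")

    @property
    def matrix(self) -> StainMatrix:
        return he_matrix() if self.stain == "HE" else lfb_nfr_matrix()


# ----------------------------------------------------------------------
# nucleus placement and rendering


def _sample_nuclei(
    rng: np.random.Generator,
    owner: np.ndarray,
    regions: tuple[RegionSpec, ...],
    pixel_size_um: float,
    max_tries_factor: int = 60,
):
    """Poisson placement with non-overlap rejection.

    Returns a list of dicts with analytic geometry (um and px).  Raises
    when the requested density cannot be placed within the bounded number
    of retries.
    """
    h, w = owner.shape
    placed: list[dict] = []
    # coarse occupancy grid for neighbour queries
    cell_um = 4.0 * math.sqrt(
        max((r.area_um2_mean + 3 * r.area_um2_sd) for r in regions) / math.pi
    )
    occ: dict[tuple[int, int], list[int]] = {}

    def neighbours(x, y):
        gx, gy = int(x // cell_um), int(y // cell_um)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                yield from occ.get((gx + dx, gy + dy), ())

    for idx, region in enumerate(regions):
        if region.nuclei_per_mm2 <= 0:
            continue
        flat = np.flatnonzero(owner.ravel() == idx)
        if flat.size == 0:
            continue
        area_mm2 = flat.size * pixel_size_um**2 / 1e6
        n = int(rng.poisson(region.nuclei_per_mm2 * area_mm2))
        tries = 0
        budget = max_tries_factor * max(n, 1)
        k = 0
        while k < n:
            if tries > budget:
                raise SlidescopeError(
                    f"nucleus density {region.nuclei_per_mm2}/mm^2 too high for "
                    f"non-overlapping placement in region {idx}"
                )
            tries += 1
            pix = flat[rng.integers(flat.size)]
            py, px = divmod(pix, w)
            x_um = (px + rng.random()) * pixel_size_um
            y_um = (py + rng.random()) * pixel_size_um
            area = max(rng.normal(region.area_um2_mean, region.area_um2_sd), 5.0)
            ecc = rng.uniform(*region.ecc_range)
            b = math.sqrt(area * math.sqrt(1 - ecc**2) / math.pi)
            a = b / math.sqrt(1 - ecc**2)
            phi = rng.uniform(0, math.pi)
            # keep the ellipse fully on the slide so truth stays analytic
            margin = a + 2 * pixel_size_um
            if not (
                margin <= x_um < w * pixel_size_um - margin
                and margin <= y_um < h * pixel_size_um - margin
            ):
                continue
            clear = True
            for j in neighbours(x_um, y_um):
                o = placed[j]
                lim = a + o["a_um"] + 2 * pixel_size_um
                if (x_um - o["x_um"]) ** 2 + (y_um - o["y_um"]) ** 2 < lim * lim:
                    clear = False
                    break
            if not clear:
                continue
            placed.append(
                dict(
                    x_um=x_um, y_um=y_um, a_um=a, b_um=b, phi=phi,
                    area_um2=math.pi * a * b, ecc=ecc, region=idx,
                )
            )
            occ.setdefault((int(x_um // cell_um), int(y_um // cell_um)), []).append(
                len(placed) - 1
            )
            k += 1
    return placed


def _paint_ellipses(shape_px, nuclei, pixel_size_um, value):
    """Rasterize ellipses (analytic parameters in um) into a density map."""
    from skimage.draw import ellipse as draw_ellipse

    h, w = shape_px
    out = np.zeros((h, w), dtype=np.float32)
    for nuc in nuclei:
        rr, cc = draw_ellipse(
            nuc["y_um"] / pixel_size_um,
            nuc["x_um"] / pixel_size_um,
            nuc["b_um"] / pixel_size_um,
            nuc["a_um"] / pixel_size_um,
            shape=(h, w),
            rotation=nuc["phi"],
        )
        out[rr, cc] = value
    return out


def _fiber_density(shape_px, orientation_deg, period_px, contrast, base):
    """Sinusoidal LFB grating at a given orientation (degrees, y down)."""
    h, w = shape_px
    xx = np.arange(w, dtype=np.float32)[None, :]
    yy = np.arange(h, dtype=np.float32)[:, None]
    th = math.radians(orientation_deg)
    u = -xx * math.sin(th) + yy * math.cos(th)  # axis perpendicular to fibers
    return base + contrast * np.cos(2.0 * np.pi * u / period_px)


def _compose_noisy(density, matrix, noise_sd, rng, chunk_rows: int = 256):
    """Beer–Lambert composition to 8-bit RGB with additive Gaussian noise.

    Processes row blocks in float32 so whole-slide scenes stay within a
    modest memory footprint.
    """
    h = density.shape[0]
    out = np.empty(density.shape, dtype=np.uint8)
    vec = matrix.vectors.astype(np.float32)
    for y0 in range(0, h, chunk_rows):
        block = density[y0 : y0 + chunk_rows].astype(np.float32)
        od = block @ vec
        intensity = 256.0 * np.exp(-od, out=od) - 1.0
        if noise_sd > 0:
            intensity += noise_sd * rng.standard_normal(
                intensity.shape, dtype=np.float32
            )
        np.clip(intensity, 0.0, 255.0, out=intensity)
        out[y0 : y0 + chunk_rows] = np.floor(intensity + 0.5).astype(np.uint8)
    return out


def _truth_records(nuclei, pixel_size_um) -> list[NucleusRecord]:
    return [
        NucleusRecord(
            id=i,
            x_um=nuc["x_um"],
            y_um=nuc["y_um"],
            area_um2=nuc["area_um2"],
            eccentricity=nuc["ecc"],
            source_row=0,
            source_col=0,
        )
        for i, nuc in enumerate(nuclei)
    ]


def render_nuclei_tile(
    size_px: tuple[int, int],
    pixel_size_um: float,
    nuclei_per_mm2: float,
    seed: int = 0,
    area_um2_mean: float = DEFAULT_AREA_UM2_MEAN,
    area_um2_sd: float = DEFAULT_AREA_UM2_SD,
    ecc_range: tuple[float, float] = DEFAULT_ECC_RANGE,
    noise_sd: float = 3.0,
    matrix: StainMatrix | None = None,
    nucleus_stain_density: float = 1.0,
    background_density: float = 0.35,
) -> tuple[np.ndarray, list[NucleusRecord]]:
    """Render one H&E-like tile; returns (8-bit RGB, exact truth records)."""
    rng = np.random.default_rng(seed)
    matrix = matrix or he_matrix()
    region = RegionSpec(
        shape=("all",),
        nuclei_per_mm2=nuclei_per_mm2,
        area_um2_mean=area_um2_mean,
        area_um2_sd=area_um2_sd,
        ecc_range=ecc_range,
    )
    owner = np.zeros(size_px, dtype=np.int32)
    nuclei = _sample_nuclei(rng, owner, (region,), pixel_size_um)
    density = np.zeros(size_px + (3,), dtype=np.float32)
    density[..., 0] = _paint_ellipses(size_px, nuclei, pixel_size_um, nucleus_stain_density)
    density[..., 1] = background_density
    rgb = _compose_noisy(density, matrix, noise_sd, rng)
    return rgb, _truth_records(nuclei, pixel_size_um)


def render_fiber_tile(
    orientation_deg: float,
    period_px: float = 16.0,
    contrast: float = 0.25,
    noise_sd: float = 3.0,
    size_px: tuple[int, int] = (512, 512),
    matrix: StainMatrix | None = None,
    lfb_base: float = 0.6,
    nfr_background: float = 0.3,
    seed: int = 0,
) -> np.ndarray:
    """Render one LFB/NFR-like tile with fibers at a known orientation."""
    if period_px < 4:
        raise ParameterError("grating period must be >= 4 px")
    rng = np.random.default_rng(seed)
    matrix = matrix or lfb_nfr_matrix()
    density = np.zeros(size_px + (3,), dtype=np.float32)
    density[..., 0] = _fiber_density(size_px, orientation_deg, period_px, contrast, lfb_base)
    density[..., 1] = nfr_background
    return _compose_noisy(density, matrix, noise_sd, rng)


# ----------------------------------------------------------------------
# whole-slide scenes


def render_scene(
    scene: SceneSpec, shape_px: tuple[int, int], pixel_size_um: float
):
    """Render the full (noisy, vignette-free) scene.

    Returns (rgb, truth_records, owner_map, subtile_orientation_frame).
    """
    rng = np.random.default_rng(scene.seed)
    owner = np.zeros(shape_px, dtype=np.int32)
    for idx, region in enumerate(scene.regions):
        if region.shape[0] != "all":
            owner[region.mask_px(shape_px, pixel_size_um)] = idx
    nuclei = _sample_nuclei(rng, owner, scene.regions, pixel_size_um)
    density = np.zeros(shape_px + (3,), dtype=np.float32)
    nuc_channel = 0 if scene.stain == "HE" else 1
    density[..., nuc_channel] += _paint_ellipses(
        shape_px, nuclei, pixel_size_um, scene.nucleus_stain_density
    )
    if scene.stain == "HE":
        density[..., 1] += scene.background_density
    else:
        density[..., 1] += scene.background_density
        lfb = np.zeros(shape_px, dtype=np.float32)
        for idx, region in enumerate(scene.regions):
            sel = owner == idx
            if region.fiber_orientation_deg is not None:
                tex = _fiber_density(
                    shape_px,
                    region.fiber_orientation_deg,
                    region.fiber_period_px,
                    region.fiber_contrast,
                    scene.lfb_base,
                )
                lfb[sel] = tex[sel]
        density[..., 0] += lfb
    rgb = _compose_noisy(density, scene.matrix, scene.noise_sd, rng)
    return rgb, _truth_records(nuclei, pixel_size_um), owner


def vignette_gain(shape_px: tuple[int, int], strength: float) -> np.ndarray:
    """Radial quadratic gain field: 1 at center, 1-strength at the corner."""
    h, w = shape_px
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    rho2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / (cy**2 + cx**2)
    return 1.0 - strength * rho2


def apply_vignette(
    tile: np.ndarray, gain: np.ndarray, offset: float, scale: float = 1.0
) -> np.ndarray:
    """Simulate uneven illumination: scene x gain x exposure scale + offset.

    ``scale`` models the exposure headroom a real acquisition keeps so
    the brightfield never saturates; with scale = (255-offset)/255 the
    brightest scene pixel maps to exactly 255 under unit gain.
    """
    out = tile.astype(np.float64) * gain[..., None] * scale + offset
    return np.floor(np.clip(out, 0.0, 255.0) + 0.5).astype(np.uint8)


@dataclass(frozen=True)
class SlidePackage:
    """Everything a synthetic slide acquisition produces on disk."""

    directory: Path
    grid: TileGrid
    truth_nuclei: list[NucleusRecord]
    truth_regions: pd.DataFrame
    scene_rgb: np.ndarray  # vignette-free noisy render (the restoration target)
    brightfield_path: Path | None
    background_path: Path | None


def render_slide(
    scene: SceneSpec,
    grid: TileGrid,
    out_dir: str | Path,
    vignette: bool = True,
) -> SlidePackage:
    """Sample one global scene, cut it into overlapping tiles and write them.

    Tiles share identical pixels in overlap strips before vignetting (one
    scene, one noise realisation).  With ``vignette`` a per-tile gain and
    offset are applied and the matching float-valued calibration pair is
    written, making the flat-field correction exactly invertible to
    within one grey level.
    """
    out_dir = Path(out_dir)
    tiles_dir = out_dir / "tiles"
    tiles_dir.mkdir(parents=True, exist_ok=True)
    shape_px = grid.slide_shape_px
    rgb, truth, owner = render_scene(scene, shape_px, grid.pixel_size_um)

    gain = vignette_gain((grid.tile_height_px, grid.tile_width_px), scene.vignette_strength)
    scale = (255.0 - scene.vignette_offset) / 255.0  # exposure headroom
    tile_paths: dict[tuple[int, int], str] = {}
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            x, y = grid.tile_origin(r, c)
            tile = rgb[y : y + grid.tile_height_px, x : x + grid.tile_width_px]
            if vignette:
                tile = apply_vignette(tile, gain, scene.vignette_offset, scale)
            rel = f"tiles/tile_r{r:03d}_c{c:03d}.tif"
            tifffile.imwrite(out_dir / rel, tile)
            tile_paths[(r, c)] = rel

    bf_path = bg_path = None
    if vignette:
        bf = (255.0 * gain * scale + scene.vignette_offset).astype(np.float32)
        bg = np.full_like(bf, scene.vignette_offset, dtype=np.float32)
        bf_path = out_dir / "brightfield.tif"
        bg_path = out_dir / "background.tif"
        tifffile.imwrite(bf_path, np.repeat(bf[..., None], 3, axis=2), photometric="rgb")
        tifffile.imwrite(bg_path, np.repeat(bg[..., None], 3, axis=2), photometric="rgb")

    full_grid = replace(grid, tile_paths=tile_paths)
    write_manifest(
        full_grid,
        out_dir,
        metadata={"stain": scene.stain, "seed": str(scene.seed),
                  "vignette": str(vignette)},
    )

    ps = grid.pixel_size_um
    region_rows = []
    for idx, region in enumerate(scene.regions):
        n_px = int((owner == idx).sum())
        region_rows.append(
            dict(
                region=idx,
                name=region.name or f"region{idx}",
                nuclei_per_mm2=region.nuclei_per_mm2,
                fiber_orientation_deg=(
                    np.nan
                    if region.fiber_orientation_deg is None
                    else region.fiber_orientation_deg
                ),
                area_mm2=n_px * ps * ps / 1e6,
            )
        )
    truth_regions = pd.DataFrame(region_rows)
    truth_regions.to_csv(out_dir / "truth_regions.csv", index=False)
    from .records import write_nucleus_table

    write_nucleus_table(truth, out_dir / "truth_nuclei.csv")
    return SlidePackage(
        directory=out_dir,
        grid=full_grid,
        truth_nuclei=truth,
        truth_regions=truth_regions,
        scene_rgb=rgb,
        brightfield_path=bf_path,
        background_path=bg_path,
    )


def demo_scene(
    seed: int = 0,
    width_um: float = 3000.0,
    height_um: float = 3000.0,
    cortex_per_mm2: float = 2473.0,
    wm_per_mm2: float = 3581.0,
    tumor_per_mm2: float = 5714.0,
) -> SceneSpec:
    """Three-band H&E demo scene echoing cortex / white matter / tumor
    cellularity magnitudes (vertical thirds, left to right)."""
    w3 = width_um / 3.0
    return SceneSpec(
        regions=(
            RegionSpec(("rect", 0, 0, w3, height_um), nuclei_per_mm2=cortex_per_mm2,
                       name="cortex"),
            RegionSpec(("rect", w3, 0, 2 * w3, height_um), nuclei_per_mm2=wm_per_mm2,
                       name="white_matter"),
            RegionSpec(("rect", 2 * w3, 0, width_um + 1, height_um),
                       nuclei_per_mm2=tumor_per_mm2, name="tumor"),
        ),
        stain="HE",
        seed=seed,
    )
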