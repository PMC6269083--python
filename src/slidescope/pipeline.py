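"""End-to-end pipeline orchestration.

One run consumes a tile-grid acquisition (or generates a synthetic one),
applies flat-field correction, composes an inspection mosaic from each
tile's unique region (tile positions are trusted from the acquisition
geometry; no cross-correlation refinement), segments nuclei per tile,
deduplicates detections across overlaps, builds the heatmap set and — on
myelin-stained slides — the fiber-orientation maps.  Outputs, the
serialized configuration and a stage-timing log land in the output
directory; reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .errors import ParameterError, PipelineError
from .fibers import FiberParams, analyze_image, render_hsv, render_rg, results_to_frame
from .geometry import TileGrid
from .heatmap import STAT_NAMES, build_heatmaps, render_heatmap
from .illumination import CalibrationPair, correct_tile
from .records import (
    deduplicate_records,
    read_manifest,
    write_nucleus_table,
)
from .segmentation import SegmentationParams, segment_tile
from .stains import BUILTIN_MATRICES, StainImage, deconvolve
from .synth import SceneSpec, demo_scene, render_slide

log = logging.getLogger("slidescope")


def _params_from_dict(cls, block: dict, section: str):
    """Build a parameter dataclass from a config block, rejecting unknown keys."""
    block = dict(block or {})
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - known
    if unknown:
        raise ParameterError(f"unknown keys in config section '{section}': {sorted(unknown)}")
    if "channel_criteria" in block and block["channel_criteria"] is not None:
        block["channel_criteria"] = {
            int(k): (float(v[0]), float(v[1]))
            for k, v in block["channel_criteria"].items()
        }
    return cls(**block)


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    ``input_dir`` points at a grid manifest directory; when absent, the
    built-in synthetic demo scene is generated under the output directory
    first.  Parameter blocks mirror the stage dataclasses one to one.
    """

    output_dir: str = "slidescope_out"
    input_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"
    stain: str = "HE"
    dedup_radius_um: float = 4.0
    kernel_size_um: float = 500.0
    synth: dict = field(default_factory=dict)
    illumination: dict = field(default_factory=dict)
    segmentation: dict = field(default_factory=dict)
    fibers: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return _params_from_dict(cls, data, "pipeline")

    def segmentation_params(self) -> SegmentationParams:
        return _params_from_dict(SegmentationParams, self.segmentation, "segmentation")

    def fiber_params(self) -> FiberParams:
        return _params_from_dict(FiberParams, self.fibers, "fibers")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def compose_mosaic(grid: TileGrid, tiles: dict[tuple[int, int], np.ndarray]) -> np.ndarray:
    """Paste tiles at their grid origins; overlaps resolved by unique regions.

    No blending: every slide pixel comes from exactly one tile, so on
    synthetic data (identical overlap pixels) the mosaic reproduces the
    scene exactly.
    """
    first = None
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            if (r, c) not in tiles:
                raise PipelineError("stitch", f"missing tile ({r}, {c})")
            t = np.asarray(tiles[(r, c)])
            if first is None:
                first = t.shape
            elif t.shape != first:
                raise PipelineError("stitch", f"tile ({r}, {c}) shape {t.shape} != {first}")
    h, w = grid.slide_shape_px
    shape = (h, w) + first[2:]
    mosaic = np.zeros(shape, dtype=np.asarray(next(iter(tiles.values()))).dtype)
    for (r, c), tile in tiles.items():
        ox, oy = grid.tile_origin(r, c)
        u = grid.unique_region(r, c)
        mosaic[oy + u.y0 : oy + u.y1, ox + u.x0 : ox + u.x1] = np.asarray(tile)[
            u.y0 : u.y1, u.x0 : u.x1
        ]
    return mosaic


def _load_tiles(grid: TileGrid, base: Path) -> dict[tuple[int, int], np.ndarray]:
    tiles = {}
    for (r, c), rel in grid.tile_paths.items():
        p = Path(rel)
        if not p.is_absolute():
            p = base / p
        tiles[(r, c)] = tifffile.imread(p) if p.suffix in (".tif", ".tiff") else iio.imread(p)
    return tiles


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the output directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    config.to_yaml(out / "config.yaml")
    timings: list[tuple[str, float]] = []
    declared: list[Path] = [out / "config.yaml"]

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s ...", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc_type is not None:
                    raise PipelineError(name, str(exc)) from exc
                timings.append((name, time.perf_counter() - self.t0))
                return False

        return _Timer()

    # ---------------- input
    with stage("input"):
        if config.input_dir is None:
            synth_block = dict(config.synth or {})
            grid_block = synth_block.pop("grid", {})
            vignette = bool(synth_block.pop("vignette", True))
            scene = demo_scene(seed=config.seed, **synth_block)
            grid = TileGrid(
                n_rows=int(grid_block.get("n_rows", 2)),
                n_cols=int(grid_block.get("n_cols", 2)),
                tile_width_px=int(grid_block.get("tile_width_px", 1024)),
                tile_height_px=int(grid_block.get("tile_height_px", 1024)),
                overlap=float(grid_block.get("overlap", 0.05)),
                pixel_size_um=float(grid_block.get("pixel_size_um", 0.54)),
            )
            package = render_slide(scene, grid, out / "synthetic", vignette=vignette)
            input_dir = package.directory
        else:
            input_dir = Path(config.input_dir)
        grid, metadata = read_manifest(input_dir)
        stain = metadata.get("stain", config.stain)
        tiles = _load_tiles(grid, input_dir)

    # ---------------- illumination
    with stage("illumination"):
        bf_path = input_dir / "brightfield.tif"
        bg_path = input_dir / "background.tif"
        if bf_path.exists() and bg_path.exists():
            calib = CalibrationPair(
                brightfield=tifffile.imread(bf_path),
                background=tifffile.imread(bg_path),
            )
            window = int((config.illumination or {}).get("median_window", 0))
            if window:
                calib = calib.median_smoothed(window)
            tiles = {rc: correct_tile(t, calib) for rc, t in tiles.items()}
            corr_dir = out / "corrected"
            corr_dir.mkdir(exist_ok=True)
            for (r, c), t in sorted(tiles.items()):
                p = corr_dir / f"tile_r{r:03d}_c{c:03d}.tif"
                tifffile.imwrite(p, t)
                declared.append(p)
        else:
            log.info("no calibration pair found; skipping correction")

    # ---------------- mosaic
    with stage("stitch"):
        mosaic = compose_mosaic(grid, tiles)
        step = max(1, max(mosaic.shape[:2]) // 2048)
        iio.imwrite(out / "overview.png", mosaic[::step, ::step])
        declared.append(out / "overview.png")

    matrix = BUILTIN_MATRICES[stain]()

    # ---------------- segmentation
    with stage("segmentation"):
        seg_params = config.segmentation_params()
        if stain == "LFB-NFR" and "nuclear_channel" not in (config.segmentation or {}):
            seg_params = dataclasses.replace(
                seg_params, nuclear_channel=1, channel_criteria={1: (0.15, float("inf"))}
            )
        records = []
        for (r, c) in sorted(tiles):
            stains_img = deconvolve(tiles[(r, c)], matrix)
            records.extend(
                segment_tile(stains_img, grid, r, c, seg_params, start_id=len(records))
            )
        records = deduplicate_records(records, radius_um=config.dedup_radius_um)
        write_nucleus_table(records, out / "nuclei.csv")
        declared.append(out / "nuclei.csv")

    # ---------------- heatmaps
    with stage("heatmap"):
        heatmaps = build_heatmaps(records, grid.slide_extent_um, config.kernel_size_um)
        for name in STAT_NAMES:
            p = out / f"heatmap_{name}.png"
            render_heatmap(heatmaps.stat(name), p)
            declared.extend([p, p.with_suffix(".csv")])

    # ---------------- fibers (myelin stains only)
    with stage("fibers"):
        if stain == "LFB-NFR":
            results = analyze_image(
                deconvolve(mosaic, matrix),
                config.fiber_params(),
                pixel_size_um=grid.pixel_size_um,
            )
            results_to_frame(results).to_csv(out / "fibers_tiles.csv", index=False)
            declared.append(out / "fibers_tiles.csv")
            if any(res.valid for res in results):
                iio.imwrite(out / "fibers_hsv.png", render_hsv(results, upscale=4))
                iio.imwrite(out / "fibers_rg.png", render_rg(results, upscale=4))
                declared.extend([out / "fibers_hsv.png", out / "fibers_rg.png"])
        else:
            log.info("stain %s: fiber analysis not applicable", stain)

    # ---------------- log
    with (out / "run.log").open("w") as fh:
        fh.write(f"slidescope pipeline run (seed={config.seed}, stain={stain})\n")
        fh.write(f"grid: {grid.n_rows}x{grid.n_cols} tiles, overlap={grid.overlap}, "
                 f"pixel_size_um={grid.pixel_size_um}\n")
        fh.write(f"nuclei: {len(records)}\n")
        for name, dt in timings:
            fh.write(f"stage {name}: {dt:.2f} s\n")
        for p in declared:
            fh.write(f"output: {p}\n")
    missing = [p for p in declared if not p.exists() or p.stat().st_size == 0]
    if missing:
        raise PipelineError("finalize", f"missing or empty outputs: {missing}")
    return out
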