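"""Nucleus records, tabular I/O and the grid manifest.

The nucleus table is a plain CSV with one row per segmented nucleus in
slide coordinates (micrometers, origin at the slide top-left, y down).
The grid manifest is a directory holding a flat key-value metadata file
plus a per-tile CSV; it round-trips a :class:`~slidescope.geometry.TileGrid`
losslessly together with opaque acquisition metadata (camera gains,
exposure, ...).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import TableParseError, ParameterError
from .geometry import TileGrid

NUCLEUS_COLUMNS = [
    "id",
    "x_um",
    "y_um",
    "area_um2",
    "eccentricity",
    "source_row",
    "source_col",
]


@dataclass(frozen=True)
class NucleusRecord:
    """One segmented nucleus in slide coordinates.

    ``x_um``/``y_um`` are the centroid in micrometers from the slide
    top-left corner (x rightward, y downward); ``area_um2`` the region
    area; ``eccentricity`` that of the second-moment-equivalent ellipse
    (0 = circle); ``source_row``/``source_col`` the tile that produced
    the detection.
    """

    id: int
    x_um: float
    y_um: float
    area_um2: float
    eccentricity: float
    source_row: int
    source_col: int

    def __post_init__(self):
        if self.area_um2 <= 0:
            raise ParameterError(f"nucleus area must be positive, got {self.area_um2}")
        if not (0.0 <= self.eccentricity < 1.0):
            raise ParameterError(
                f"eccentricity must be in [0, 1), got {self.eccentricity}"
            )


def write_nucleus_table(records: list[NucleusRecord], path: str | Path) -> None:
    """Write records as CSV (floats at 6 decimals); header always present."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(NUCLEUS_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.id,
                    f"{r.x_um:.6f}",
                    f"{r.y_um:.6f}",
                    f"{r.area_um2:.6f}",
                    f"{r.eccentricity:.6f}",
                    r.source_row,
                    r.source_col,
                ]
            )


def read_nucleus_table(path: str | Path) -> list[NucleusRecord]:
    """Read a nucleus CSV; malformed rows raise :class:`TableParseError`."""
    path = Path(path)
    with path.open() as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise TableParseError(f"{path}: empty file", line=1) from None
        if header != NUCLEUS_COLUMNS:
            raise TableParseError(
                f"{path}: bad header {header!r}, expected {NUCLEUS_COLUMNS!r}", line=1
            )
        records = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(NUCLEUS_COLUMNS):
                raise TableParseError(
                    f"{path}: expected {len(NUCLEUS_COLUMNS)} fields, got {len(row)}",
                    line=lineno,
                )
            try:
                records.append(
                    NucleusRecord(
                        id=int(row[0]),
                        x_um=float(row[1]),
                        y_um=float(row[2]),
                        area_um2=float(row[3]),
                        eccentricity=float(row[4]),
                        source_row=int(row[5]),
                        source_col=int(row[6]),
                    )
                )
            except (ValueError, ParameterError) as exc:
                raise TableParseError(f"{path}: {exc}", line=lineno) from exc
    return records


def records_to_frame(records: list[NucleusRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=NUCLEUS_COLUMNS)


# ----------------------------------------------------------------------
# Grid manifest

_MANIFEST_FILE = "manifest.txt"
_TILES_FILE = "tiles.csv"


def write_manifest(
    grid: TileGrid, directory: str | Path, metadata: dict[str, str] | None = None
) -> None:
    """Serialize a grid (plus opaque metadata) into ``directory``.

    Writes ``manifest.txt`` (flat ``key: value`` lines) and ``tiles.csv``
    (``row,col,path``).  Metadata keys are stored with a ``meta.`` prefix
    so they cannot collide with geometry fields.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fields = {
        "n_rows": grid.n_rows,
        "n_cols": grid.n_cols,
        "tile_width_px": grid.tile_width_px,
        "tile_height_px": grid.tile_height_px,
        "overlap": repr(grid.overlap),
        "pixel_size_um": repr(grid.pixel_size_um),
        "serpentine": grid.serpentine,
    }
    with (directory / _MANIFEST_FILE).open("w") as fh:
        for k, v in fields.items():
            fh.write(f"{k}: {v}\n")
        for k, v in (metadata or {}).items():
            fh.write(f"meta.{k}: {v}\n")
    with (directory / _TILES_FILE).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["row", "col", "path"])
        for (r, c), p in sorted(grid.tile_paths.items()):
            writer.writerow([r, c, p])


def read_manifest(directory: str | Path) -> tuple[TileGrid, dict[str, str]]:
    """Inverse of :func:`write_manifest`; returns (grid, metadata)."""
    directory = Path(directory)
    raw: dict[str, str] = {}
    with (directory / _MANIFEST_FILE).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if ":" not in line:
                raise TableParseError(
                    f"{directory / _MANIFEST_FILE}: expected 'key: value'", line=lineno
                )
            k, v = line.split(":", 1)
            raw[k.strip()] = v.strip()
    tile_paths: dict[tuple[int, int], str] = {}
    with (directory / _TILES_FILE).open() as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["row", "col", "path"]:
            raise TableParseError(f"{directory / _TILES_FILE}: bad header", line=1)
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                tile_paths[(int(row[0]), int(row[1]))] = row[2]
            except (ValueError, IndexError) as exc:
                raise TableParseError(
                    f"{directory / _TILES_FILE}: {exc}", line=lineno
                ) from exc
    try:
        grid = TileGrid(
            n_rows=int(raw["n_rows"]),
            n_cols=int(raw["n_cols"]),
            tile_width_px=int(raw["tile_width_px"]),
            tile_height_px=int(raw["tile_height_px"]),
            overlap=float(raw["overlap"]),
            pixel_size_um=float(raw["pixel_size_um"]),
            serpentine=raw["serpentine"] == "True",
            tile_paths=tile_paths,
        )
    except KeyError as exc:
        raise TableParseError(f"manifest missing field {exc}") from exc
    metadata = {k[5:]: v for k, v in raw.items() if k.startswith("meta.")}
    return grid, metadata


def deduplicate_records(
    records: list[NucleusRecord], radius_um: float = 4.0
) -> list[NucleusRecord]:
    """Merge duplicate detections of one nucleus from different tiles.

    A nucleus whose pixel support straddles a unique-region boundary can be
    reported both by the owning tile (in full) and by the neighbour (as a
    clipped fragment whose centroid falls inside the neighbour's unique
    region).  Records from *different* source tiles closer than
    ``radius_um`` are taken to be the same nucleus and the larger-area
    record is kept.  Records are re-numbered sequentially.
    """
    if not records:
        return []
    from scipy.spatial import cKDTree

    import numpy as np

    pts = np.array([(r.x_um, r.y_um) for r in records])
    tree = cKDTree(pts)
    order = sorted(range(len(records)), key=lambda i: -records[i].area_um2)
    keep = [True] * len(records)
    claimed = [False] * len(records)
    for i in order:
        if claimed[i]:
            continue
        claimed[i] = True
        for j in tree.query_ball_point(pts[i], radius_um):
            if j == i or claimed[j]:
                continue
            src_i = (records[i].source_row, records[i].source_col)
            src_j = (records[j].source_row, records[j].source_col)
            if src_i != src_j:
                keep[j] = False
                claimed[j] = True
    out = [r for r, k in zip(records, keep) if k]
    return [
        NucleusRecord(
            id=n,
            x_um=r.x_um,
            y_um=r.y_um,
            area_um2=r.area_um2,
            eccentricity=r.eccentricity,
            source_row=r.source_row,
            source_col=r.source_col,
        )
        for n, r in enumerate(out)
    ]


def ellipse_eccentricity(a: float, b: float) -> float:
    """Eccentricity of an ellipse with semi-axes a >= b."""
    a, b = max(a, b), min(a, b)
    return math.sqrt(1.0 - (b / a) ** 2)
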