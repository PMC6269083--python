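"""Tile-grid acquisition geometry.

A whole slide is digitised as a rectangular grid of overlapping camera
fields of view.  Tiles are acquired in a serpentine (boustrophedon) stage
path and share a small user-defined overlap fraction so that every piece
of tissue is seen completely by at least one tile.  All coordinates follow
the raster convention: 0-based, x rightward, y downward, rectangles
half-open.

The default pixel size of 0.54 um/px corresponds to a ~1.4 mm field of
view imaged onto a 2592-px-wide sensor; it is an inferred default and
should be overridden with the calibrated value of the actual setup.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

from .errors import ParameterError

#: micrometers per pixel for a ~1.4 mm FOV on a 2592-px sensor width
DEFAULT_PIXEL_SIZE_UM = 0.54

#: typical user-defined tile overlap fraction
DEFAULT_OVERLAP = 0.05


@dataclass(frozen=True)
class Rect:
    """Half-open pixel rectangle [x0, x1) x [y0, y1)."""

    x0: int
    y0: int
    x1: int
    y1: int

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1


@dataclass(frozen=True)
class TileGrid:
    """Geometry of a tile-grid acquisition.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions.
    tile_width_px, tile_height_px
        Camera tile size in pixels.
    overlap
        Fraction of each tile shared with its neighbour, in [0, 1).
    pixel_size_um
        Micrometers per pixel.
    serpentine
        Whether the acquisition path alternates direction on odd rows.
    tile_paths
        Optional map (row, col) -> image file path.
    """

    n_rows: int
    n_cols: int
    tile_width_px: int
    tile_height_px: int
    overlap: float = DEFAULT_OVERLAP
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    serpentine: bool = True
    tile_paths: dict[tuple[int, int], str] = field(default_factory=dict)

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise ParameterError("grid must have at least one row and column")
        if self.tile_width_px < 1 or self.tile_height_px < 1:
            raise ParameterError("tile dimensions must be positive")
        if not (0.0 <= self.overlap < 1.0):
            raise ParameterError(f"overlap must be in [0, 1), got {self.overlap}")
        if self.pixel_size_um <= 0:
            raise ParameterError("pixel_size_um must be positive")
        if self.tile_paths:
            expected = {(r, c) for r in range(self.n_rows) for c in range(self.n_cols)}
            if set(self.tile_paths) != expected:
                raise ParameterError(
                    "tile_paths must map every (row, col) of the grid exactly once"
                )

    # ------------------------------------------------------------------
    @property
    def n_tiles(self) -> int:
        return self.n_rows * self.n_cols

    def _check_indices(self, row: int, col: int) -> None:
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(
                f"tile index ({row}, {col}) outside {self.n_rows}x{self.n_cols} grid"
            )

    def tile_origin(self, row: int, col: int) -> tuple[int, int]:
        """Slide-pixel coordinates (x, y) of the tile's top-left corner.

        Adjacent origins are spaced by the tile size times (1 - overlap),
        rounded to the nearest pixel.
        """
        self._check_indices(row, col)
        x = round(col * self.tile_width_px * (1.0 - self.overlap))
        y = round(row * self.tile_height_px * (1.0 - self.overlap))
        return x, y

    def serpentine_index(self, acquisition_index: int) -> tuple[int, int]:
        """Map an acquisition-order index to (row, col).

        On a serpentine path even rows run left-to-right and odd rows
        right-to-left; otherwise plain row-major order.
        """
        if not (0 <= acquisition_index < self.n_tiles):
            raise IndexError(
                f"acquisition index {acquisition_index} outside [0, {self.n_tiles})"
            )
        row, k = divmod(acquisition_index, self.n_cols)
        if self.serpentine and row % 2 == 1:
            return row, (self.n_cols - 1) - k
        return row, k

    def acquisition_order(self) -> Iterator[tuple[int, int]]:
        for i in range(self.n_tiles):
            yield self.serpentine_index(i)

    def unique_region(self, row: int, col: int) -> Rect:
        """Tile-local half-open rectangle owned exclusively by this tile.

        Interior tiles own the span up to the next tile's origin; the last
        row/column extends to the full tile.  The union of unique regions
        over the grid partitions the slide exactly.
        """
        self._check_indices(row, col)
        x0, y0 = self.tile_origin(row, col)
        if col == self.n_cols - 1:
            x_end = self.tile_width_px
        else:
            x_end = self.tile_origin(row, col + 1)[0] - x0
        if row == self.n_rows - 1:
            y_end = self.tile_height_px
        else:
            y_end = self.tile_origin(row + 1, col)[1] - y0
        return Rect(0, 0, x_end, y_end)

    @property
    def slide_shape_px(self) -> tuple[int, int]:
        """(height, width) of the full mosaic in slide pixels."""
        x_last, y_last = self.tile_origin(self.n_rows - 1, self.n_cols - 1)
        return y_last + self.tile_height_px, x_last + self.tile_width_px

    @property
    def slide_extent_um(self) -> tuple[float, float]:
        """(width_um, height_um) of the full mosaic."""
        h, w = self.slide_shape_px
        return w * self.pixel_size_um, h * self.pixel_size_um

    def px_to_um(self, x_px: float, y_px: float) -> tuple[float, float]:
        return x_px * self.pixel_size_um, y_px * self.pixel_size_um
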