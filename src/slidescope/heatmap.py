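"""Kernel-wise cellularity and nuclear morphometry heatmaps.

Nucleus records are binned into non-overlapping square evaluation kernels
(half-open membership by centroid).  Per kernel the maps hold the nucleus
count, cellularity (nuclei per mm^2, using the kernel's true area — edge
kernels clipped by the slide boundary use their clipped area), and the
mean, population SD and coefficient of variation of nuclear area and
eccentricity.  Kernels without nuclei are *undefined* (NaN), not zero:
zero cellularity is a measurement, absence of detections is not
distinguished from absence of tissue at this level.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib
import numpy as np

from .errors import ParameterError, SlidescopeError
from .records import NucleusRecord

STAT_NAMES = (
    "cellularity",
    "mean_area",
    "sd_area",
    "cov_area",
    "mean_ecc",
    "sd_ecc",
    "cov_ecc",
)


@dataclass(frozen=True)
class HeatmapSet:
    """Per-kernel statistics over a slide.

    Arrays have shape (ny, nx); ``n`` is the integer count, the float
    statistics are NaN where undefined (empty kernel, or zero-mean for a
    COV).  ``kernel_area_mm2`` holds each kernel's true (boundary-clipped)
    area.
    """

    kernel_size_um: float
    extent_um: tuple[float, float]  # (width, height)
    n: np.ndarray
    kernel_area_mm2: np.ndarray
    cellularity: np.ndarray
    mean_area: np.ndarray
    sd_area: np.ndarray
    cov_area: np.ndarray
    mean_ecc: np.ndarray
    sd_ecc: np.ndarray
    cov_ecc: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.n.shape

    def stat(self, name: str) -> np.ndarray:
        if name not in STAT_NAMES:
            raise ParameterError(f"unknown statistic {name!r}; one of {STAT_NAMES}")
        return getattr(self, name)

    def kernel_centers_um(self) -> tuple[np.ndarray, np.ndarray]:
        """(cx, cy) arrays of shape (ny, nx), centers of the clipped kernels."""
        ny, nx = self.shape
        k = self.kernel_size_um
        w, h = self.extent_um
        x0 = np.arange(nx) * k
        y0 = np.arange(ny) * k
        x1 = np.minimum(x0 + k, w)
        y1 = np.minimum(y0 + k, h)
        cx = (x0 + x1) / 2.0
        cy = (y0 + y1) / 2.0
        return np.broadcast_to(cx, (ny, nx)).copy(), np.broadcast_to(
            cy[:, None], (ny, nx)
        ).copy()


def _moments(values: np.ndarray, idx: np.ndarray, nk: int):
    """Per-kernel mean and population SD of ``values`` grouped by kernel idx."""
    cnt = np.bincount(idx, minlength=nk).astype(float)
    s1 = np.bincount(idx, weights=values, minlength=nk)
    s2 = np.bincount(idx, weights=values * values, minlength=nk)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(cnt > 0, s1 / np.maximum(cnt, 1), np.nan)
        var = np.where(cnt > 0, s2 / np.maximum(cnt, 1) - mean**2, np.nan)
        sd = np.sqrt(np.maximum(var, 0.0))
        cov = np.where(mean > 0, sd / mean, np.nan)
    mean[cnt == 0] = np.nan
    sd[cnt == 0] = np.nan
    return mean, sd, cov


def build_heatmaps(
    records: list[NucleusRecord],
    extent_um: tuple[float, float],
    kernel_size_um: float = 500.0,
) -> HeatmapSet:
    """Bin nucleus records into square kernels and compute per-kernel stats.

    ``extent_um`` is (width, height) of the slide.  Records outside the
    extent raise an error naming the offending ids.  The sum of kernel
    counts equals the number of input records exactly.
    """
    if kernel_size_um <= 0:
        raise ParameterError("kernel_size_um must be positive")
    w, h = extent_um
    nx = max(1, int(np.ceil(w / kernel_size_um)))
    ny = max(1, int(np.ceil(h / kernel_size_um)))
    x = np.array([r.x_um for r in records])
    y = np.array([r.y_um for r in records])
    if len(records):
        outside = (x < 0) | (x >= w) | (y < 0) | (y >= h)
        if outside.any():
            ids = [records[i].id for i in np.flatnonzero(outside)[:20]]
            raise SlidescopeError(f"records outside slide extent: ids {ids}")
    ix = (x // kernel_size_um).astype(int) if len(records) else np.array([], int)
    iy = (y // kernel_size_um).astype(int) if len(records) else np.array([], int)
    flat = iy * nx + ix
    nk = ny * nx

    n = np.bincount(flat, minlength=nk)
    # true (clipped) kernel areas in mm^2
    xw = np.minimum((np.arange(nx) + 1) * kernel_size_um, w) - np.arange(nx) * kernel_size_um
    yh = np.minimum((np.arange(ny) + 1) * kernel_size_um, h) - np.arange(ny) * kernel_size_um
    area_mm2 = np.outer(yh, xw) / 1e6

    areas = np.array([r.area_um2 for r in records])
    eccs = np.array([r.eccentricity for r in records])
    mean_a, sd_a, cov_a = _moments(areas, flat, nk)
    mean_e, sd_e, cov_e = _moments(eccs, flat, nk)
    cellularity = np.where(n > 0, n / area_mm2.ravel(), np.nan)

    def grid(a):
        return a.reshape(ny, nx)

    return HeatmapSet(
        kernel_size_um=kernel_size_um,
        extent_um=(float(w), float(h)),
        n=grid(n),
        kernel_area_mm2=area_mm2,
        cellularity=grid(cellularity),
        mean_area=grid(mean_a),
        sd_area=grid(sd_a),
        cov_area=grid(cov_a),
        mean_ecc=grid(mean_e),
        sd_ecc=grid(sd_e),
        cov_ecc=grid(cov_e),
    )


def region_summary(
    heatmaps: HeatmapSet,
    region,
    statistic: str = "cellularity",
) -> dict[str, float]:
    """Descriptive statistics of a per-kernel map over a region.

    ``region`` selects kernels by their centers: either a boolean array of
    the kernel-grid shape, or an object with a ``contains``/(x, y) test —
    a shapely geometry, or any callable ``f(x_um, y_um) -> bool``.
    Returns mean, population SD, median and IQR (linear-interpolation,
    type-7 quantiles) over the *defined* kernels in the region.
    """
    values = heatmaps.stat(statistic)
    if isinstance(region, np.ndarray) and region.dtype == bool:
        if region.shape != heatmaps.shape:
            raise ParameterError("region mask shape does not match kernel grid")
        sel = region
    else:
        cx, cy = heatmaps.kernel_centers_um()
        if callable(region):
            sel = np.vectorize(region)(cx, cy).astype(bool)
        else:  # shapely geometry
            from shapely.geometry import Point

            sel = np.array(
                [region.contains(Point(px, py)) for px, py in zip(cx.ravel(), cy.ravel())]
            ).reshape(heatmaps.shape)
    if not sel.any():
        raise SlidescopeError("region does not intersect any kernel")
    vals = values[sel]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise SlidescopeError("region contains no defined kernels")
    q1, q3 = np.percentile(vals, [25, 75])  # linear interpolation (type 7)
    return {
        "mean": float(np.mean(vals)),
        "sd": float(np.std(vals)),
        "median": float(np.median(vals)),
        "iqr": float(q3 - q1),
        "n_kernels": int(vals.size),
    }


def render_heatmap(
    values: np.ndarray,
    out_path: str | Path,
    colormap: str = "viridis",
    undefined_color: tuple[int, int, int] = (40, 40, 40),
    upscale: int = 16,
) -> np.ndarray:
    """Render one per-kernel map to an 8-bit PNG plus a raw-value CSV sidecar.

    Defined kernels are min-max scaled over the map; undefined (NaN)
    kernels get the reserved ``undefined_color``.  The sidecar CSV (same
    stem, ``.csv``) holds the raw matrix.
    """
    import imageio.v3 as iio

    values = np.asarray(values, dtype=float)
    defined = ~np.isnan(values)
    if not defined.any():
        raise SlidescopeError("cannot render an all-undefined map")
    vmin = values[defined].min()
    vmax = values[defined].max()
    span = vmax - vmin if vmax > vmin else 1.0
    norm = np.where(defined, (values - vmin) / span, 0.0)
    cmap = matplotlib.colormaps[colormap]
    rgb = (cmap(norm)[..., :3] * 255).astype(np.uint8)
    rgb[~defined] = undefined_color
    if upscale > 1:
        rgb = np.kron(rgb, np.ones((upscale, upscale, 1), dtype=np.uint8))
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out_path, rgb)
    np.savetxt(out_path.with_suffix(".csv"), values, delimiter=",", fmt="%.6g")
    return rgb
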