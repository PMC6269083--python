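"""Nuclei segmentation from the hematoxylin density channel.

Pipeline (fixed order): Phansalkar local thresholding -> size pre-filter
-> distance-transform watershed splitting of touching nuclei -> per-channel
mean-density refinement (rejects hematoxylin-poor objects such as corpora
amylacea) -> size filter -> morphometry.

The Phansalkar threshold is designed for low-contrast stained nuclei:
a pixel of the [0,1]-normalized density image is foreground iff its value
exceeds

    T = m * (1 + p*exp(-q*m) + k*(s/R - 1))

with m, s the mean and standard deviation in a square window around the
pixel and p, q, k, R the published constants (2, 10, 0.25, 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.measure import regionprops
from skimage.segmentation import relabel_sequential, watershed

from .errors import ParameterError
from .geometry import TileGrid
from .records import NucleusRecord
from .stains import StainImage

_INF = float("inf")


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the nuclei segmentation pipeline.

    ``channel_criteria`` maps stain-channel index (0 = first stain, 1 =
    second, 2 = residual) to (min, max) acceptable mean density; objects
    violating any bound are rejected in the refinement step.  The
    hematoxylin lower bound and the window/threshold constants default to
    values calibrated on the synthetic fixtures; the size window follows
    the <2500 um^2 retention rule with a small lower bound against
    speckle.
    """

    window_radius_px: int = 15
    p: float = 2.0
    q: float = 10.0
    k: float = 0.25
    R: float = 0.5
    min_area_um2: float = 10.0
    max_area_um2: float = 2500.0
    channel_criteria: dict[int, tuple[float, float]] = field(
        default_factory=lambda: {0: (0.15, _INF)}
    )
    min_seed_distance_px: int = 7
    seed_smooth_sigma_px: float = 1.0
    density_norm: float = 2.0  # density mapped to 1.0 before thresholding
    nuclear_channel: int = 0  # stain channel holding the nuclear stain

    def __post_init__(self):
        if self.window_radius_px < 1:
            raise ParameterError("window_radius_px must be >= 1")
        if not (self.max_area_um2 > self.min_area_um2 >= 0):
            raise ParameterError("need max_area_um2 > min_area_um2 >= 0")


def phansalkar_threshold_map(
    density01: np.ndarray, params: SegmentationParams
) -> np.ndarray:
    """Per-pixel Phansalkar threshold T = m(1 + p e^{-qm} + k(s/R - 1)).

    m and s are the mean and standard deviation over a (2*radius+1) square
    window with reflective boundary handling.
    """
    img = np.asarray(density01, dtype=np.float64)
    size = 2 * params.window_radius_px + 1
    if size > min(img.shape):
        raise ParameterError(
            f"window size {size} exceeds image extent {min(img.shape)}"
        )
    m = ndimage.uniform_filter(img, size=size, mode="reflect")
    m2 = ndimage.uniform_filter(img * img, size=size, mode="reflect")
    s = np.sqrt(np.maximum(m2 - m * m, 0.0))
    return m * (1.0 + params.p * np.exp(-params.q * m) + params.k * (s / params.R - 1.0))


def phansalkar_threshold(density01: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Local Phansalkar threshold of a [0,1] image; returns a boolean mask."""
    img = np.asarray(density01, dtype=np.float64)
    return img > phansalkar_threshold_map(img, params)


def size_filter(
    mask_or_labels: np.ndarray,
    min_area_um2: float,
    max_area_um2: float,
    pixel_size_um: float,
) -> np.ndarray:
    """Drop components with area outside [min_area_um2, max_area_um2).

    Accepts a boolean mask (connected components are labelled first) or an
    integer label image; remaining labels are recompacted to 1..n.
    """
    if pixel_size_um <= 0:
        raise ParameterError("pixel_size_um must be positive")
    arr = np.asarray(mask_or_labels)
    if arr.dtype == bool:
        labels, _ = ndimage.label(arr)
    else:
        labels = arr.astype(np.int64, copy=True)
    if labels.max() == 0:
        return labels
    px_area = pixel_size_um**2
    counts = np.bincount(labels.ravel())
    areas = counts * px_area
    bad = (areas >= max_area_um2) | (areas < min_area_um2)
    bad[0] = False
    labels[bad[labels]] = 0
    return relabel_sequential(labels)[0]


def watershed_split(mask: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Split touching nuclei with a distance-transform watershed.

    Seeds are local maxima of the (lightly smoothed) Euclidean distance
    transform, separated by at least ``min_seed_distance_px``; components
    without a detected peak keep a single seed at their distance maximum.
    Ridge (watershed-line) pixels are set to background, so output
    foreground differs from input only by those ridges.  Seeds are
    numbered in (y, x) order for determinism.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int64)
    edt = ndimage.distance_transform_edt(mask)
    smooth = (
        ndimage.gaussian_filter(edt, params.seed_smooth_sigma_px)
        if params.seed_smooth_sigma_px > 0
        else edt
    )
    comps, n_comp = ndimage.label(mask)
    peaks = peak_local_max(
        smooth,
        min_distance=params.min_seed_distance_px,
        labels=comps,
        exclude_border=False,
    )
    seeded = set(comps[tuple(peaks.T)]) if len(peaks) else set()
    missing = [c for c in range(1, n_comp + 1) if c not in seeded]
    if missing:
        extra = ndimage.maximum_position(smooth, labels=comps, index=missing)
        peaks = np.vstack([peaks.reshape(-1, 2), np.asarray(extra, dtype=int)])
    order = np.lexsort((peaks[:, 1], peaks[:, 0]))  # (y, x) ordering
    peaks = peaks[order]
    markers = np.zeros(mask.shape, dtype=np.int64)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-edt, markers=markers, mask=mask, watershed_line=True)
    return relabel_sequential(labels)[0]


def channel_refine(
    labels: np.ndarray,
    stains: StainImage,
    criteria: dict[int, tuple[float, float]],
) -> np.ndarray:
    """Reject objects whose per-channel mean density violates any bound.

    Removes e.g. corpora amylacea, which are eosin-rich but hematoxylin
    poor.  Surviving labels are recompacted.
    """
    labels = np.asarray(labels)
    if labels.shape != stains.density.shape[:2]:
        raise ParameterError("labels and stain image are not aligned")
    n = labels.max()
    if n == 0 or not criteria:
        return relabel_sequential(labels.astype(np.int64))[0]
    keep = np.ones(n + 1, dtype=bool)
    idx = np.arange(1, n + 1)
    for ch, (lo, hi) in criteria.items():
        means = ndimage.mean(stains.density[..., ch], labels=labels, index=idx)
        keep[1:] &= (means >= lo) & (means <= hi)
    keep[0] = False
    out = labels.astype(np.int64, copy=True)
    out[~keep[out]] = 0
    return relabel_sequential(out)[0]


def measure_nuclei(
    labels: np.ndarray,
    grid: TileGrid,
    row: int,
    col: int,
    start_id: int = 0,
) -> list[NucleusRecord]:
    """Morphometry of labelled nuclei in slide coordinates.

    Centroid (um, slide frame via the tile origin), area (px count times
    pixel area) and second-moment eccentricity per label.  Detections
    whose centroid falls outside the tile's unique region are discarded:
    with overlapping tiles they belong to a neighbouring tile.
    """
    ox, oy = grid.tile_origin(row, col)
    unique = grid.unique_region(row, col)
    ps = grid.pixel_size_um
    records = []
    nid = start_id
    for prop in regionprops(np.asarray(labels)):
        cy, cx = prop.centroid
        if not unique.contains(cx, cy):
            continue
        records.append(
            NucleusRecord(
                id=nid,
                x_um=(ox + cx) * ps,
                y_um=(oy + cy) * ps,
                area_um2=prop.area * ps * ps,
                eccentricity=min(prop.eccentricity, 1.0 - 1e-12),
                source_row=row,
                source_col=col,
            )
        )
        nid += 1
    return records


def segment_tile(
    stains: StainImage,
    grid: TileGrid,
    row: int,
    col: int,
    params: SegmentationParams | None = None,
    start_id: int = 0,
    return_labels: bool = False,
):
    """Full segmentation of one deconvolved tile; returns nucleus records.

    Stage order is fixed: threshold -> size pre-filter -> watershed ->
    channel refinement -> size filter -> measurement.
    """
    params = params or SegmentationParams()
    ps = grid.pixel_size_um
    density01 = np.clip(
        stains.density[..., params.nuclear_channel] / params.density_norm, 0.0, 1.0
    )
    mask = phansalkar_threshold(density01, params)
    labels = size_filter(mask, params.min_area_um2, params.max_area_um2, ps)
    labels = watershed_split(labels > 0, params)
    labels = channel_refine(labels, stains, params.channel_criteria)
    labels = size_filter(labels, params.min_area_um2, params.max_area_um2, ps)
    records = measure_nuclei(labels, grid, row, col, start_id=start_id)
    if return_labels:
        return records, labels
    return records
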