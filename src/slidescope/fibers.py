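"""Gradient-based fiber-orientation mapping of myelin-stained sections.

Myelinated fiber tracts in a luxol-fast-blue (LFB) stained section appear
as oriented texture in the LFB density channel.  The image is partitioned
into square subtiles; in each subtile the Sobel gradient direction of
every usable pixel is pooled into a Gaussian-kernel orientation density P
over [0, 180) (gradient sign carries no orientation information, so
angles are folded modulo 180 and the kernel is wrapped with period 180).
A strong gradient in one direction implies fibers running perpendicular
to it, so the dominant fiber orientation is

    theta = (argmax P + 90) mod 180        (degrees, ccw from the image
                                            x-axis; y points down)

Two scalar quality measures accompany theta:

    M_rel = max(P) / (max(P) + min(P))     in [0.5, 1]; 0.5 = isotropic
    I_rel = 3 * sum(I_LFB) / sum(I_total)  in [0, 3]; LFB share of the
                                            total deconvolved density

Subtiles with too few usable pixels (impurities excluded by a density
threshold) or too little gradient signal are flagged invalid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InvalidTileError, ParameterError
from .stains import StainImage, StainMatrix, deconvolve


@dataclass(frozen=True)
class FiberParams:
    """Parameters of the orientation analysis.

    ``impurity_threshold`` excludes pixels whose ``impurity_channel``
    density (default: residual) exceeds it — dust and pigment load the
    residual channel.  ``kde_weighted`` optionally weights the orientation
    density by gradient magnitude.  ``fold_angles=False`` reproduces a
    raw-direction fit on (-180, 180] for comparison.
    """

    subtile_px: int = 64
    kde_bandwidth_deg: float = 5.0
    eval_grid_deg: float = 1.0
    impurity_threshold: float = 1.0
    impurity_channel: int = 2
    min_valid_fraction: float = 0.5
    min_mean_magnitude: float = 0.01
    kde_weighted: bool = False
    fold_angles: bool = True

    def __post_init__(self):
        if self.subtile_px < 8:
            raise ParameterError("subtile_px must be >= 8")
        if self.kde_bandwidth_deg <= 0:
            raise ParameterError("kde_bandwidth_deg must be positive")


@dataclass(frozen=True)
class FiberTileResult:
    """Orientation estimate for one subtile (invalid fields are NaN)."""

    row: int
    col: int
    x_um: float  # subtile center, slide frame
    y_um: float
    theta_deg: float
    m_rel: float
    i_rel: float
    mean_mag: float
    valid: bool


def gradient_field(density: np.ndarray, fold: bool = True):
    """Sobel gradient direction (degrees) and magnitude of a 2-D raster.

    Directions are folded to [0, 180) by default (orientation, not
    direction); with ``fold=False`` raw atan2 angles in (-180, 180] are
    returned.  The Sobel kernels are normalized so a unit ramp has unit
    magnitude.
    """
    img = np.asarray(density, dtype=np.float64)
    if img.ndim != 2:
        raise ParameterError("gradient_field expects a single-channel raster")
    gx = ndimage.sobel(img, axis=1) / 8.0
    gy = ndimage.sobel(img, axis=0) / 8.0
    ang = np.degrees(np.arctan2(gy, gx))
    if fold:
        ang = np.mod(ang, 180.0)
    mag = np.hypot(gx, gy)
    return ang, mag


def orientation_density(
    g_dir: np.ndarray,
    g_mag: np.ndarray,
    mask: np.ndarray,
    params: FiberParams,
):
    """Wrapped Gaussian-kernel density of gradient orientations.

    Returns (grid_deg, P) with P evaluated on a regular grid over the
    period (180 deg folded, 360 unfolded); replicas of every sample at
    +-period make the estimate circular.  P integrates to 1 over one
    period.  Raises :class:`InvalidTileError` when no masked pixel has
    positive gradient magnitude.
    """
    period = 180.0 if params.fold_angles else 360.0
    sel = np.asarray(mask, bool) & (np.asarray(g_mag) > 0)
    angles = np.asarray(g_dir, dtype=np.float64)[sel]
    if angles.size == 0:
        raise InvalidTileError("no valid pixels with nonzero gradient")
    weights = np.asarray(g_mag, dtype=np.float64)[sel] if params.kde_weighted else None
    grid = np.arange(0.0, period, params.eval_grid_deg)
    h = params.kde_bandwidth_deg
    n_wrap = max(1, int(np.ceil(5.0 * h / period)))
    shifts = np.arange(-n_wrap, n_wrap + 1) * period
    # (grid, samples) difference, accumulated over wrap replicas
    p = np.zeros_like(grid)
    norm = 1.0 / (np.sqrt(2.0 * np.pi) * h)
    wsum = angles.size if weights is None else weights.sum()
    for s in shifts:
        d = grid[:, None] - (angles[None, :] + s)
        k = np.exp(-0.5 * (d / h) ** 2)
        if weights is not None:
            k = k * weights[None, :]
        p += k.sum(axis=1)
    p *= norm / wsum
    return grid, p


def dominant_orientation(grid: np.ndarray, p: np.ndarray) -> float:
    """Fiber orientation: perpendicular to the density's dominant gradient."""
    return float((grid[int(np.argmax(p))] + 90.0) % 180.0)


def relative_magnitude(p: np.ndarray) -> float:
    """M_rel = max(P)/(max(P)+min(P)) over the evaluation grid; in [0.5, 1]."""
    pmax = float(np.max(p))
    pmin = float(np.min(p))
    if pmax == 0.0:
        return 0.5
    return pmax / (pmax + pmin)


def relative_intensity(stains: StainImage, mask: np.ndarray | None = None) -> float:
    """I_rel = 3 * sum(first-stain density) / sum(all densities) over valid pixels."""
    d = stains.density
    if mask is not None:
        d = d[np.asarray(mask, bool)]
    total = float(d.sum())
    if total <= 0:
        raise InvalidTileError("zero total stain density")
    return 3.0 * float(d[..., 0].sum() if d.ndim == 3 else d[:, 0].sum()) / total


_NAN_RESULT = dict(theta_deg=np.nan, m_rel=np.nan, i_rel=np.nan)


def analyze_image(
    stains: StainImage,
    params: FiberParams | None = None,
    pixel_size_um: float = 1.0,
    origin_px: tuple[int, int] = (0, 0),
) -> list[FiberTileResult]:
    """Per-subtile orientation analysis of a deconvolved LFB image.

    The image is cut into ``subtile_px`` squares (partial edge subtiles
    participate when they retain enough valid pixels); gradients are
    computed once on the full LFB density channel.  Results are returned
    in row-major subtile order.
    """
    params = params or FiberParams()
    lfb = stains.density[..., 0]
    g_dir, g_mag = gradient_field(lfb, fold=params.fold_angles)
    impurity = stains.density[..., params.impurity_channel] > params.impurity_threshold
    valid_px = ~impurity
    h, w = lfb.shape
    t = params.subtile_px
    n_rows = int(np.ceil(h / t))
    n_cols = int(np.ceil(w / t))
    ox, oy = origin_px
    results = []
    for r in range(n_rows):
        for c in range(n_cols):
            ys, xs = slice(r * t, min((r + 1) * t, h)), slice(c * t, min((c + 1) * t, w))
            sub_mask = valid_px[ys, xs]
            n_valid = int(sub_mask.sum())
            cx_um = (ox + (xs.start + xs.stop) / 2.0) * pixel_size_um
            cy_um = (oy + (ys.start + ys.stop) / 2.0) * pixel_size_um
            sub_mag = g_mag[ys, xs]
            mean_mag = float(sub_mag[sub_mask].mean()) if n_valid else 0.0
            ok = (
                n_valid >= params.min_valid_fraction * t * t
                and mean_mag >= params.min_mean_magnitude
            )
            if ok:
                try:
                    grid, p = orientation_density(
                        g_dir[ys, xs], sub_mag, sub_mask, params
                    )
                    sub_stains = StainImage(
                        density=stains.density[ys, xs], matrix=stains.matrix
                    )
                    res = dict(
                        theta_deg=dominant_orientation(grid, p),
                        m_rel=relative_magnitude(p),
                        i_rel=relative_intensity(sub_stains, sub_mask),
                    )
                except InvalidTileError:
                    ok, res = False, _NAN_RESULT
            else:
                res = _NAN_RESULT
            results.append(
                FiberTileResult(
                    row=r, col=c, x_um=cx_um, y_um=cy_um,
                    mean_mag=mean_mag, valid=bool(ok), **res,
                )
            )
    return results


def analyze_slide(
    rgb: np.ndarray,
    matrix: StainMatrix,
    params: FiberParams | None = None,
    pixel_size_um: float = 1.0,
) -> list[FiberTileResult]:
    """Deconvolve an RGB LFB/NFR image and run the orientation analysis."""
    return analyze_image(deconvolve(rgb, matrix), params, pixel_size_um)


def _result_grid(results: list[FiberTileResult]):
    n_rows = max(r.row for r in results) + 1
    n_cols = max(r.col for r in results) + 1
    return n_rows, n_cols


def _percentile_clip(values: np.ndarray, pct: float = 99.0) -> np.ndarray:
    hi = np.percentile(values, pct)
    if hi <= 0:
        hi = values.max() if values.max() > 0 else 1.0
    return np.clip(values / hi, 0.0, 1.0)


def render_hsv(results: list[FiberTileResult], upscale: int = 1) -> np.ndarray:
    """Orientation map in HSV: hue = theta/180, V = I_rel*M_rel*mean |grad|.

    V is normalized by clipping at the 99th percentile over valid
    subtiles; invalid subtiles are black.  Returns an 8-bit RGB image at
    one pixel per subtile (times ``upscale``).
    """
    from matplotlib.colors import hsv_to_rgb

    valid = [r for r in results if r.valid]
    if not valid:
        raise InvalidTileError("no valid subtiles to render")
    n_rows, n_cols = _result_grid(results)
    hsv = np.zeros((n_rows, n_cols, 3))
    v_raw = np.array([r.i_rel * r.m_rel * r.mean_mag for r in valid])
    v_norm = _percentile_clip(v_raw)
    for r, v in zip(valid, v_norm):
        hsv[r.row, r.col] = (r.theta_deg / 180.0, 1.0, v)
    rgb = np.floor(hsv_to_rgb(hsv) * 255 + 0.5).astype(np.uint8)
    if upscale > 1:
        rgb = np.kron(rgb, np.ones((upscale, upscale, 1), dtype=np.uint8))
    return rgb


def render_rg(results: list[FiberTileResult], upscale: int = 1) -> np.ndarray:
    """Horizontal/vertical projection map.

    Horizontally oriented fibers load the R channel, vertical ones the G
    channel: R = w*|cos theta|, G = w*|sin theta|, B = 0, where w =
    I_rel*M_rel normalized by a 99th-percentile clip, so the (R, G) color
    vector norm equals w*255.
    """
    valid = [r for r in results if r.valid]
    if not valid:
        raise InvalidTileError("no valid subtiles to render")
    n_rows, n_cols = _result_grid(results)
    img = np.zeros((n_rows, n_cols, 3), dtype=np.uint8)
    w_norm = _percentile_clip(np.array([r.i_rel * r.m_rel for r in valid]))
    for r, w in zip(valid, w_norm):
        th = np.radians(r.theta_deg)
        img[r.row, r.col, 0] = int(np.floor(255.0 * w * abs(np.cos(th)) + 0.5))
        img[r.row, r.col, 1] = int(np.floor(255.0 * w * abs(np.sin(th)) + 0.5))
    if upscale > 1:
        img = np.kron(img, np.ones((upscale, upscale, 1), dtype=np.uint8))
    return img


def results_to_frame(results: list[FiberTileResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            dict(
                row=r.row, col=r.col, x_um=r.x_um, y_um=r.y_um,
                theta_deg=r.theta_deg, m_rel=r.m_rel, i_rel=r.i_rel,
                mean_mag=r.mean_mag, valid=r.valid,
            )
            for r in results
        ]
    )
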