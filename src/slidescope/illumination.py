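"""Flat-field illumination correction.

Without Koehler illumination each camera tile carries a smooth
multiplicative shading field (vignetting) plus an additive sensor offset.
Both are measured once with two calibration exposures taken without a
specimen: a *brightfield* image (light path open) and a *background*
image (no light).  Each tile is then corrected per pixel and channel as

    I_corrected = 255 * (I_original - I_background) / (I_brightfield - I_background)

clamped to [0, 255] and rounded half-up to 8-bit.  The correction is
applied per RGB channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .errors import CalibrationError, DimensionError


@dataclass(frozen=True)
class CalibrationPair:
    """Brightfield/background calibration images (same shape).

    ``validate`` enforces brightfield > background at every pixel/channel;
    a denominator of zero or less would make the correction undefined.
    """

    brightfield: np.ndarray
    background: np.ndarray

    def __post_init__(self):
        bf = np.asarray(self.brightfield)
        bg = np.asarray(self.background)
        if bf.shape != bg.shape:
            raise DimensionError(
                f"brightfield shape {bf.shape} != background shape {bg.shape}"
            )

    def validate(self) -> None:
        diff = self.brightfield.astype(np.float64) - self.background.astype(np.float64)
        bad = int(np.count_nonzero(diff < 1.0))
        if bad:
            raise CalibrationError(
                f"brightfield exceeds background by <1 grey level at {bad} "
                "pixel/channel positions"
            )

    def median_smoothed(self, window: int) -> "CalibrationPair":
        """Median-filter both images (dust suppression); window in pixels."""
        if window < 1:
            return self
        size = (window, window) + (1,) * (self.brightfield.ndim - 2)
        return CalibrationPair(
            brightfield=median_filter(self.brightfield, size=size),
            background=median_filter(self.background, size=size),
        )


def correct_tile(original: np.ndarray, calib: CalibrationPair) -> np.ndarray:
    """Flat-field correct one tile; returns an 8-bit array of the same shape.

    Values outside [0, 255] (e.g. specular pixels brighter than the
    brightfield) are clamped; rounding is half-up.
    """
    original = np.asarray(original)
    if original.shape != calib.brightfield.shape:
        raise DimensionError(
            f"tile shape {original.shape} != calibration shape "
            f"{calib.brightfield.shape}"
        )
    calib.validate()
    o = original.astype(np.float64)
    bg = calib.background.astype(np.float64)
    bf = calib.brightfield.astype(np.float64)
    corrected = 255.0 * (o - bg) / (bf - bg)
    corrected = np.clip(corrected, 0.0, 255.0)
    return np.floor(corrected + 0.5).astype(np.uint8)  # round half-up
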