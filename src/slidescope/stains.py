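"""Color deconvolution of transmitted-light histology images.

Co-localised absorbing stains combine multiplicatively in transmission
(Beer–Lambert), hence additively in optical density

    OD_c = -ln((I_c + 1) / 256),     c in {R, G, B}

(the +1 offset avoids log(0) on fully dark pixels; white maps to OD 0).
Each stain has a characteristic unit-norm direction in OD-RGB space; a
pixel's OD vector is the stain concentrations times the stain matrix, so
concentrations are recovered by inverting that 3x3 system per pixel.

The hematoxylin/eosin vectors are the published Ruifrok–Johnston values.
No canonical vectors exist for luxol fast blue / nuclear fast red; the
built-in LFB-NFR matrix is a documented estimate (blue stain absorbing
red>green, red stain absorbing green>blue) and should be replaced with a
slide-specific calibration when available.  Downstream analysis operates
on DENSITY channels (high = more stain).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateMatrixError

_COND_LIMIT = 1e8


def _unit_rows(m: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(m, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise DegenerateMatrixError("zero stain vector")
    return m / norms


@dataclass(frozen=True)
class StainMatrix:
    """Three unit-norm stain vectors in OD-RGB space (rows: stain1, stain2, residual)."""

    vectors: np.ndarray
    name: str = "custom"

    def __post_init__(self):
        v = np.asarray(self.vectors, dtype=np.float64)
        if v.shape != (3, 3):
            raise DegenerateMatrixError(f"stain matrix must be 3x3, got {v.shape}")
        norms = np.linalg.norm(v, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise DegenerateMatrixError(f"stain vectors must be unit norm, got {norms}")
        if np.linalg.cond(v) > _COND_LIMIT:
            raise DegenerateMatrixError(f"stain matrix '{self.name}' is singular")
        object.__setattr__(self, "vectors", v)

    @classmethod
    def from_pair(cls, v1, v2, name: str = "custom") -> "StainMatrix":
        """Complete two stain vectors with a residual row (normalized cross
        product), orthogonal to both."""
        v1 = np.asarray(v1, dtype=np.float64)
        v2 = np.asarray(v2, dtype=np.float64)
        v12 = _unit_rows(np.stack([v1, v2]))
        cross = np.cross(v12[0], v12[1])
        n = np.linalg.norm(cross)
        if n < 1e-8:
            raise DegenerateMatrixError("stain vectors are parallel")
        return cls(np.vstack([v12, cross / n]), name=name)

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.vectors)

    def channel_names(self) -> tuple[str, str, str]:
        if self.name == "HE":
            return ("hematoxylin", "eosin", "residual")
        if self.name == "LFB-NFR":
            return ("lfb", "nfr", "residual")
        return ("stain1", "stain2", "residual")


def he_matrix() -> StainMatrix:
    """Ruifrok–Johnston hematoxylin/eosin matrix plus residual row."""
    return StainMatrix.from_pair(
        [0.650, 0.704, 0.286], [0.072, 0.990, 0.105], name="HE"
    )


def lfb_nfr_matrix() -> StainMatrix:
    """Estimated luxol-fast-blue / nuclear-fast-red matrix (see module docs)."""
    return StainMatrix.from_pair(
        [0.74, 0.61, 0.28], [0.21, 0.84, 0.50], name="LFB-NFR"
    )


BUILTIN_MATRICES = {"HE": he_matrix, "LFB-NFR": lfb_nfr_matrix}


def od_transform(rgb: np.ndarray) -> np.ndarray:
    """8-bit RGB -> optical density per channel: OD = -ln((I+1)/256)."""
    rgb = np.asarray(rgb, dtype=np.float64)
    return -np.log((rgb + 1.0) / 256.0)


def od_to_rgb8(od: np.ndarray) -> np.ndarray:
    """Inverse of :func:`od_transform` with 8-bit quantization (round half-up)."""
    i = 256.0 * np.exp(-np.asarray(od, dtype=np.float64)) - 1.0
    return np.floor(np.clip(i, 0.0, 255.0) + 0.5).astype(np.uint8)


def compose(density: np.ndarray, matrix: StainMatrix) -> np.ndarray:
    """Beer–Lambert forward composition of (H, W, 3) stain densities to 8-bit RGB.

    Exact inverse of :func:`deconvolve` up to quantization and clamping.
    """
    od = np.asarray(density, dtype=np.float64) @ matrix.vectors
    return od_to_rgb8(od)


@dataclass(frozen=True)
class StainImage:
    """Per-stain density channels of one deconvolved image.

    ``density`` has shape (H, W, 3) in stain order (stain1, stain2,
    residual); concentrations are non-negative (negative solutions are
    clamped to zero).  ``transmission8`` renders each channel as the 8-bit
    transmitted intensity round(255*exp(-c)): 255 where no stain.
    """

    density: np.ndarray
    matrix: StainMatrix

    @property
    def transmission8(self) -> np.ndarray:
        return np.floor(255.0 * np.exp(-self.density) + 0.5).astype(np.uint8)

    def channel(self, name_or_index) -> np.ndarray:
        if isinstance(name_or_index, str):
            idx = self.matrix.channel_names().index(name_or_index)
        else:
            idx = int(name_or_index)
        return self.density[..., idx]


def deconvolve(rgb: np.ndarray, matrix: StainMatrix) -> StainImage:
    """Unmix an 8-bit RGB image into per-stain densities.

    Solves OD = c . M per pixel and clamps negative concentrations to 0.
    """
    od = od_transform(rgb)
    density = od @ matrix.inverse
    np.maximum(density, 0.0, out=density)
    return StainImage(density=density, matrix=matrix)
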