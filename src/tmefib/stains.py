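"""Color deconvolution of brightfield histology by optical density.

Transmitted intensity follows Beer-Lambert: each stain attenuates light along
a characteristic unit vector in optical-density (OD) space, so a pixel's OD
is a nonnegative linear mix of the stain vectors and per-pixel stain
concentrations are recovered by inverting the 3x3 stain matrix.

Default vectors are the published H&E and H-DAB OD triplets (Ruifrok &
Johnston's calibration); both are configurable.  When only two stains are
supplied the third row is completed with the normalized orthogonal residual
so the matrix is invertible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StainMatrix",
    "HE_STAINS",
    "HDAB_STAINS",
    "rgb_to_od",
    "od_to_rgb",
    "deconvolve",
    "separate_stains",
]

#: OD quantization guard (one intensity unit), per the forward model
_EPS = 1.0


@dataclass(frozen=True)
class StainMatrix:
    """Rows are unit OD vectors, one per named stain."""

    vectors: np.ndarray  # (3, 3) float
    names: tuple[str, str, str]

    def __post_init__(self):
        v = np.asarray(self.vectors, dtype=float)
        if v.shape != (3, 3):
            raise ValueError("stain matrix must be 3x3")
        if np.any(v < -1e-12):
            raise ValueError("stain vectors must be nonnegative")
        norms = np.linalg.norm(v, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero stain vector")
        object.__setattr__(self, "vectors", v / norms[:, None])

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.vectors))

    @classmethod
    def from_two_stains(cls, v1, v2, names=("stain1", "stain2", "residual")):
        """Complete a 2-stain basis with the unit orthogonal residual.

        The cross product of the two vectors is sign-flipped so its largest
        component is positive and negatives are clamped to zero before
        renormalizing (OD vectors are physically nonnegative).
        """
        v1 = np.asarray(v1, float) / np.linalg.norm(v1)
        v2 = np.asarray(v2, float) / np.linalg.norm(v2)
        res = np.cross(v1, v2)
        if res[np.argmax(np.abs(res))] < 0:
            res = -res
        res = np.clip(res, 0.0, None)
        if np.linalg.norm(res) == 0:
            raise ValueError("stain vectors are collinear")
        return cls(np.stack([v1, v2, res / np.linalg.norm(res)]), tuple(names))


#: hematoxylin / eosin / residual (Ruifrok & Johnston H&E calibration)
HE_STAINS = StainMatrix.from_two_stains(
    (0.644211, 0.716556, 0.266844),
    (0.092789, 0.954111, 0.283111),
    names=("hematoxylin", "eosin", "residual"),
)

#: hematoxylin / DAB / residual
HDAB_STAINS = StainMatrix.from_two_stains(
    (0.650, 0.704, 0.286),
    (0.269, 0.570, 0.776),
    names=("hematoxylin", "dab", "residual"),
)


def rgb_to_od(image: np.ndarray, white_level: float = 255.0) -> np.ndarray:
    """Per-channel optical density OD = -log10((I + 1) / white_level), >= 0."""
    if white_level <= 0:
        raise ValueError("white_level must be positive")
    img = np.asarray(image, dtype=float)
    od = -np.log10((img + _EPS) / white_level)
    return np.clip(od, 0.0, None)


def od_to_rgb(od: np.ndarray, white_level: float = 255.0) -> np.ndarray:
    """Inverse of :func:`rgb_to_od` (intensities clipped to [0, white])."""
    img = white_level * np.power(10.0, -np.asarray(od, dtype=float)) - _EPS
    return np.clip(img, 0.0, white_level)


def deconvolve(od: np.ndarray, stains: StainMatrix = HE_STAINS, clip: bool = True):
    """Per-pixel stain concentrations from an OD raster.

    Solves ``od = conc @ M`` for ``conc`` with M the stain matrix; negative
    concentrations (noise outside the stain simplex) are clamped to zero.
    Returns ``(concentrations, clamped_fraction)`` where concentrations has
    one channel per stain in matrix order.
    """
    m = stains.vectors
    if stains.condition_number > 1e6:
        raise np.linalg.LinAlgError("stain matrix is singular or near-singular")
    od = np.asarray(od, dtype=float)
    conc = od.reshape(-1, 3) @ np.linalg.inv(m)
    clamped = float((conc < -1e-9).mean()) if clip else 0.0
    if clip:
        conc = np.clip(conc, 0.0, None)
    return conc.reshape(od.shape), clamped


def separate_stains(image: np.ndarray, stains: StainMatrix = HE_STAINS, white_level: float = 255.0):
    """RGB image -> dict of named concentration rasters (+ clamp report)."""
    conc, clamped = deconvolve(rgb_to_od(image, white_level), stains)
    out = {name: conc[..., i] for i, name in enumerate(stains.names)}
    out["_clamped_fraction"] = clamped
    return out
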