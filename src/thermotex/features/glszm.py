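"""Gray Level Size Zone Matrix features.

A zone is an 8-connected component of pixels sharing one gray level
(labelled with ``scipy.ndimage.label``).  Unlike GLRLM there is no direction
to average over: a single matrix describes the whole patch.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .quantize import QuantizedPatch

_EPS = np.spacing(1.0)

GLSZM_NAMES = (
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "ZonePercentage",
    "GrayLevelVariance",
    "ZoneVariance",
    "ZoneEntropy",
    "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)

_STRUCT8 = np.ones((3, 3), dtype=bool)


def size_zone_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Zone count matrix ``Z[i-1, s-1]`` (gray level i, zone size s)."""
    mat = np.zeros((n_levels, levels.size), dtype=np.float64)
    for lvl in np.unique(levels):
        labelled, n_zones = ndimage.label(levels == lvl, structure=_STRUCT8)
        if n_zones == 0:
            continue
        sizes = np.bincount(labelled.ravel())[1:]
        np.add.at(mat, (lvl - 1, sizes - 1), 1.0)
    return mat[:, : max(1, int(np.max(np.nonzero(mat.sum(axis=0))[0])) + 1)]


def glszm_features(q: QuantizedPatch) -> dict[str, float]:
    """16 GLSZM features of the patch."""
    mat = size_zone_matrix(q.levels, q.n_levels)
    nz = mat.sum()
    p = mat / nz
    i = np.arange(1, mat.shape[0] + 1, dtype=np.float64)[:, None]
    s = np.arange(1, mat.shape[1] + 1, dtype=np.float64)[None, :]
    pg = mat.sum(axis=1)
    ps = mat.sum(axis=0)
    mu_i = np.sum(i * p)
    mu_s = np.sum(s * p)
    return {
        "SmallAreaEmphasis": float(np.sum(mat / s**2) / nz),
        "LargeAreaEmphasis": float(np.sum(mat * s**2) / nz),
        "GrayLevelNonUniformity": float(np.sum(pg**2) / nz),
        "GrayLevelNonUniformityNormalized": float(np.sum(pg**2) / nz**2),
        "SizeZoneNonUniformity": float(np.sum(ps**2) / nz),
        "SizeZoneNonUniformityNormalized": float(np.sum(ps**2) / nz**2),
        "ZonePercentage": float(nz / q.levels.size),
        "GrayLevelVariance": float(np.sum(p * (i - mu_i) ** 2)),
        "ZoneVariance": float(np.sum(p * (s - mu_s) ** 2)),
        "ZoneEntropy": float(-np.sum(p * np.log2(p + _EPS))),
        "LowGrayLevelZoneEmphasis": float(np.sum(mat / i**2) / nz),
        "HighGrayLevelZoneEmphasis": float(np.sum(mat * i**2) / nz),
        "SmallAreaLowGrayLevelEmphasis": float(np.sum(mat / (i**2 * s**2)) / nz),
        "SmallAreaHighGrayLevelEmphasis": float(np.sum(mat * i**2 / s**2) / nz),
        "LargeAreaLowGrayLevelEmphasis": float(np.sum(mat * s**2 / i**2) / nz),
        "LargeAreaHighGrayLevelEmphasis": float(np.sum(mat * i**2 * s**2) / nz),
    }
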