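"""Gray Level Dependence Matrix features.

For each pixel, the dependence count is 1 plus the number of 8-neighbours
(distance 1) whose gray level differs from the centre by at most ``alpha``
(default 0) — i.e. the size of the dependent set including the centre pixel,
which keeps every dependence index >= 1 so the small-dependence emphases are
well defined.  ``P(i, d)`` counts pixels of level i with dependence d.
"""

from __future__ import annotations

import numpy as np

from .quantize import QuantizedPatch

_EPS = np.spacing(1.0)

GLDM_NAMES = (
    "SmallDependenceEmphasis",
    "LargeDependenceEmphasis",
    "GrayLevelNonUniformity",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "GrayLevelVariance",
    "DependenceVariance",
    "DependenceEntropy",
    "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)

_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def dependence_matrix(levels: np.ndarray, n_levels: int, alpha: int = 0) -> np.ndarray:
    """Dependence count matrix ``P[i-1, d-1]``, d = dependent-set size."""
    h, w = levels.shape
    dep = np.ones(levels.shape, dtype=np.int64)  # the centre pixel itself
    for dy, dx in _OFFSETS:
        ys = slice(max(0, dy), h + min(0, dy))
        xs = slice(max(0, dx), w + min(0, dx))
        ys_n = slice(max(0, -dy), h + min(0, -dy))
        xs_n = slice(max(0, -dx), w + min(0, -dx))
        dep[ys, xs] += (
            np.abs(levels[ys, xs] - levels[ys_n, xs_n]) <= alpha
        ).astype(np.int64)
    mat = np.zeros((n_levels, 9), dtype=np.float64)
    np.add.at(mat, (levels.ravel() - 1, dep.ravel() - 1), 1.0)
    return mat


def gldm_features(q: QuantizedPatch, alpha: int = 0) -> dict[str, float]:
    """The 14 GLDM features of the patch."""
    mat = dependence_matrix(q.levels, q.n_levels, alpha=alpha)
    nz = mat.sum()
    p = mat / nz
    i = np.arange(1, mat.shape[0] + 1, dtype=np.float64)[:, None]
    d = np.arange(1, mat.shape[1] + 1, dtype=np.float64)[None, :]
    pg = mat.sum(axis=1)
    pd = mat.sum(axis=0)
    mu_i = np.sum(i * p)
    mu_d = np.sum(d * p)
    return {
        "SmallDependenceEmphasis": float(np.sum(mat / d**2) / nz),
        "LargeDependenceEmphasis": float(np.sum(mat * d**2) / nz),
        "GrayLevelNonUniformity": float(np.sum(pg**2) / nz),
        "DependenceNonUniformity": float(np.sum(pd**2) / nz),
        "DependenceNonUniformityNormalized": float(np.sum(pd**2) / nz**2),
        "GrayLevelVariance": float(np.sum(p * (i - mu_i) ** 2)),
        "DependenceVariance": float(np.sum(p * (d - mu_d) ** 2)),
        "DependenceEntropy": float(-np.sum(p * np.log2(p + _EPS))),
        "LowGrayLevelEmphasis": float(np.sum(mat / i**2) / nz),
        "HighGrayLevelEmphasis": float(np.sum(mat * i**2) / nz),
        "SmallDependenceLowGrayLevelEmphasis": float(np.sum(mat / (i**2 * d**2)) / nz),
        "SmallDependenceHighGrayLevelEmphasis": float(np.sum(mat * i**2 / d**2) / nz),
        "LargeDependenceLowGrayLevelEmphasis": float(np.sum(mat * d**2 / i**2) / nz),
        "LargeDependenceHighGrayLevelEmphasis": float(np.sum(mat * i**2 * d**2) / nz),
    }
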