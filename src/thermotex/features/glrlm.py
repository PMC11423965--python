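"""Gray Level Run Length Matrix features.

A run is a maximal sequence of consecutive pixels with the same gray level
along one of the four principal directions (0, 45, 90, 135 degrees).  The 16
features are computed on each direction's run-length matrix and averaged
over directions.
"""

from __future__ import annotations

import numpy as np

from .quantize import QuantizedPatch

_EPS = np.spacing(1.0)

GLRLM_NAMES = (
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "GrayLevelVariance",
    "RunVariance",
    "RunEntropy",
    "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)


def _direction_lines(levels: np.ndarray, direction: str) -> list[np.ndarray]:
    h, w = levels.shape
    if direction == "0":
        return list(levels)
    if direction == "90":
        return list(levels.T)
    if direction == "45":  # up-right diagonals
        f = np.fliplr(levels)
        return [f.diagonal(k) for k in range(-h + 1, w)]
    if direction == "135":
        return [levels.diagonal(k) for k in range(-h + 1, w)]
    raise ValueError(direction)


def run_length_matrix(levels: np.ndarray, n_levels: int, direction: str) -> np.ndarray:
    """Run-length count matrix ``R[i-1, l-1]`` for one direction."""
    lines = _direction_lines(levels, direction)
    # concatenate lines with a 0 sentinel (levels are >= 1) so one pass finds
    # every run boundary
    max_len = max(len(ln) for ln in lines)
    flat = np.empty(sum(len(ln) + 1 for ln in lines), dtype=np.int64)
    pos = 0
    for ln in lines:
        flat[pos : pos + len(ln)] = ln
        flat[pos + len(ln)] = 0
        pos += len(ln) + 1
    boundaries = np.flatnonzero(np.diff(flat)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(flat)]))
    vals = flat[starts]
    keep = vals > 0
    lengths = (ends - starts)[keep]
    vals = vals[keep]
    mat = np.zeros((n_levels, max_len), dtype=np.float64)
    np.add.at(mat, (vals - 1, lengths - 1), 1.0)
    return mat


def _features_one(mat: np.ndarray, n_pixels: int) -> dict[str, float]:
    nr = mat.sum()
    p = mat / nr
    i = np.arange(1, mat.shape[0] + 1, dtype=np.float64)[:, None]
    l = np.arange(1, mat.shape[1] + 1, dtype=np.float64)[None, :]
    pg = mat.sum(axis=1)
    pr = mat.sum(axis=0)
    mu_i = np.sum(i * p)
    mu_l = np.sum(l * p)
    return {
        "ShortRunEmphasis": float(np.sum(mat / l**2) / nr),
        "LongRunEmphasis": float(np.sum(mat * l**2) / nr),
        "GrayLevelNonUniformity": float(np.sum(pg**2) / nr),
        "GrayLevelNonUniformityNormalized": float(np.sum(pg**2) / nr**2),
        "RunLengthNonUniformity": float(np.sum(pr**2) / nr),
        "RunLengthNonUniformityNormalized": float(np.sum(pr**2) / nr**2),
        "RunPercentage": float(nr / n_pixels),
        "GrayLevelVariance": float(np.sum(p * (i - mu_i) ** 2)),
        "RunVariance": float(np.sum(p * (l - mu_l) ** 2)),
        "RunEntropy": float(-np.sum(p * np.log2(p + _EPS))),
        "LowGrayLevelRunEmphasis": float(np.sum(mat / i**2) / nr),
        "HighGrayLevelRunEmphasis": float(np.sum(mat * i**2) / nr),
        "ShortRunLowGrayLevelEmphasis": float(np.sum(mat / (i**2 * l**2)) / nr),
        "ShortRunHighGrayLevelEmphasis": float(np.sum(mat * i**2 / l**2) / nr),
        "LongRunLowGrayLevelEmphasis": float(np.sum(mat * l**2 / i**2) / nr),
        "LongRunHighGrayLevelEmphasis": float(np.sum(mat * i**2 * l**2) / nr),
    }


def glrlm_features(q: QuantizedPatch) -> dict[str, float]:
    """16 GLRLM features averaged over the four directions."""
    n_pixels = q.levels.size
    out = {name: 0.0 for name in GLRLM_NAMES}
    for direction in ("0", "45", "90", "135"):
        mat = run_length_matrix(q.levels, q.n_levels, direction)
        feats = _features_one(mat, n_pixels)
        for name in GLRLM_NAMES:
            out[name] += feats[name]
    return {name: v / 4.0 for name, v in out.items()}
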