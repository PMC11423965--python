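"""Neighbouring Gray Tone Difference Matrix features.

For each gray level i, ``s(i)`` accumulates the absolute difference between
every pixel of level i and the mean of its valid 8-neighbourhood (edge
pixels use only the neighbours that exist).  The five classic descriptors
are Coarseness, Contrast, Busyness, Complexity and Strength.

Degenerate conventions: with a single occupied gray level Contrast,
Busyness, Complexity and Strength are 0, and Coarseness saturates at 1e6
when its denominator vanishes.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .quantize import QuantizedPatch

NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.float64)
_COARSENESS_CAP = 1e6


def ngtdm_table(levels: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(n_i, s_i)`` arrays indexed by gray level - 1."""
    vals = levels.astype(np.float64)
    nbr_sum = ndimage.convolve(vals, _KERNEL, mode="constant", cval=0.0)
    nbr_cnt = ndimage.convolve(np.ones_like(vals), _KERNEL, mode="constant", cval=0.0)
    diff = np.abs(vals - nbr_sum / nbr_cnt)
    n_i = np.bincount(levels.ravel() - 1, minlength=n_levels).astype(np.float64)
    s_i = np.bincount(levels.ravel() - 1, weights=diff.ravel(), minlength=n_levels)
    return n_i, s_i


def ngtdm_features(q: QuantizedPatch) -> dict[str, float]:
    """The 5 NGTDM features of the patch."""
    n_i, s_i = ngtdm_table(q.levels, q.n_levels)
    n_pix = q.levels.size
    p_i = n_i / n_pix
    present = p_i > 0
    n_gp = int(present.sum())
    i_vals = np.arange(1, q.n_levels + 1, dtype=np.float64)

    ip = i_vals[present]
    pp = p_i[present]
    sp = s_i[present]

    denom_coarse = float(np.sum(pp * sp))
    coarseness = 1.0 / denom_coarse if denom_coarse > 0 else _COARSENESS_CAP
    coarseness = min(coarseness, _COARSENESS_CAP)

    if n_gp > 1:
        di = ip[:, None] - ip[None, :]
        pij = pp[:, None] * pp[None, :]
        contrast = (
            float(np.sum(pij * di**2)) / (n_gp * (n_gp - 1)) * float(np.sum(sp)) / n_pix
        )
        denom_busy = float(np.sum(np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :])))
        busyness = float(np.sum(pp * sp)) / denom_busy if denom_busy > 0 else 0.0
        complexity = float(
            np.sum(
                np.abs(di)
                * (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :])
                / (pp[:, None] + pp[None, :])
            )
        ) / n_pix
        denom_strength = float(np.sum(sp))
        strength = (
            float(np.sum((pp[:, None] + pp[None, :]) * di**2)) / denom_strength
            if denom_strength > 0
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }
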