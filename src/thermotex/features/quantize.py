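"""Gray-level quantization of image patches.

All higher-order texture matrices (GLCM, GLRLM, GLSZM, NGTDM, GLDM) operate on
a patch whose intensities have been discretized to integer gray levels
``1..Ng``.  Two discretization modes are provided:

``fixed_bin_count``
    The patch's own dynamic range ``[min, max]`` is divided into ``Ng`` equal
    bins.  A constant patch maps entirely to level 1.  This keeps the matrix
    dimensions identical across patches with different dynamic ranges, which
    stabilises feature scales across an ablation sequence.

``fixed_bin_width``
    Intensities are binned with a fixed width starting at the patch minimum;
    the number of occupied levels then varies per patch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class QuantizedPatch:
    """A patch discretized to integer gray levels ``1..n_levels``."""

    levels: np.ndarray  # int array, values in 1..n_levels
    n_levels: int
    original: np.ndarray

    def __post_init__(self) -> None:
        if self.levels.min() < 1 or self.levels.max() > self.n_levels:
            raise ValueError("quantized levels outside 1..n_levels")


def quantize(
    patch: np.ndarray,
    n_bins: int = 32,
    mode: str = "fixed_bin_count",
    bin_width: float = 8.0,
) -> QuantizedPatch:
    """Discretize ``patch`` to integer gray levels.

    Parameters
    ----------
    patch:
        2-D array of intensities (any numeric dtype).
    n_bins:
        Number of gray levels ``Ng`` for ``fixed_bin_count`` mode.
    mode:
        ``"fixed_bin_count"`` (default) or ``"fixed_bin_width"``.
    bin_width:
        Intensity width of one level in ``fixed_bin_width`` mode.
    """
    patch = np.asarray(patch)
    if patch.size == 0:
        raise ValueError("empty patch")
    if mode == "fixed_bin_count":
        if n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        lo = float(patch.min())
        hi = float(patch.max())
        if hi == lo:  # constant patch: everything is level 1
            levels = np.ones(patch.shape, dtype=np.int64)
        else:
            scaled = (patch.astype(np.float64) - lo) / (hi - lo) * n_bins
            levels = np.minimum(scaled.astype(np.int64) + 1, n_bins)
        return QuantizedPatch(levels=levels, n_levels=n_bins, original=patch)
    if mode == "fixed_bin_width":
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        lo = float(patch.min())
        levels = ((patch.astype(np.float64) - lo) // bin_width).astype(np.int64) + 1
        return QuantizedPatch(
            levels=levels, n_levels=int(levels.max()), original=patch
        )
    raise ValueError(f"unknown quantization mode: {mode!r}")
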