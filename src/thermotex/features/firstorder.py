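"""First-order (histogram) statistics of a grayscale patch.

Nineteen descriptors of the intensity distribution, following the IBSI
reference definitions.  All moments are population moments (denominator
``N``).  Entropy and uniformity are computed on the discretized histogram
(same fixed-bin-count quantization used by the texture matrices), so that a
constant patch has entropy 0 and uniformity 1.
"""

from __future__ import annotations

import numpy as np

from .quantize import quantize

FIRSTORDER_NAMES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "Percentile10",
    "Percentile90",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "StandardDeviation",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)


def first_order(
    patch: np.ndarray, n_bins: int = 32, pixel_spacing: float = 1.0
) -> dict[str, float]:
    """Compute the 19 first-order features of ``patch``.

    ``pixel_spacing`` (mm/px) scales TotalEnergy by the pixel area.
    Skewness and kurtosis of a constant patch are reported as 0 (the
    documented degenerate convention; kurtosis is the non-excess Pearson
    kurtosis, so a Gaussian patch scores ~3).
    """
    x = np.asarray(patch, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty patch")
    n = x.size
    mean = x.mean()
    dev = x - mean
    var = float(np.mean(dev**2))
    sd = np.sqrt(var)
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    if var > 0:
        skew = float(np.mean(dev**3)) / sd**3
        kurt = float(np.mean(dev**4)) / var**2
    else:
        skew = 0.0
        kurt = 0.0
    q = quantize(patch, n_bins=n_bins)
    p = np.bincount(q.levels.ravel(), minlength=q.n_levels + 1)[1:] / n
    p_nz = p[p > 0]
    energy = float(np.sum(x**2))
    return {
        "Energy": energy,
        "TotalEnergy": energy * pixel_spacing**2,
        "Entropy": float(-np.sum(p_nz * np.log2(p_nz))),
        "Minimum": float(x.min()),
        "Percentile10": float(p10),
        "Percentile90": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(dev))),
        "RobustMeanAbsoluteDeviation": float(
            np.mean(np.abs(robust - robust.mean()))
        ),
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "StandardDeviation": float(sd),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": float(np.sum(p**2)),
    }
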