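"""The 104-feature grayscale texture battery.

Seven families, in this fixed order:

====================  ==  =============================================
first order           19  histogram statistics of raw intensities
2-D shape             10  geometry of the (square) ROI mask
GLCM                  24  co-occurrence statistics, 4 angles averaged
GLRLM                 16  run-length statistics, 4 directions averaged
GLSZM                 16  8-connected size-zone statistics
NGTDM                  5  neighbourhood gray-tone difference statistics
GLDM                  14  dependence-count statistics
====================  ==  =============================================

Feature names are namespaced ``family_Feature`` (e.g. ``glcm_ClusterProminence``).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .firstorder import FIRSTORDER_NAMES, first_order
from .gldm import GLDM_NAMES, gldm_features
from .glcm import GLCM_NAMES, glcm_features
from .glrlm import GLRLM_NAMES, glrlm_features
from .glszm import GLSZM_NAMES, glszm_features
from .ngtdm import NGTDM_NAMES, ngtdm_features
from .normalize import NormalizationStats, apply_normalizer, fit_normalizer
from .quantize import QuantizedPatch, quantize
from .shape2d import SHAPE2D_NAMES, shape2d

FAMILY_NAMES = {
    "firstorder": FIRSTORDER_NAMES,
    "shape2d": SHAPE2D_NAMES,
    "glcm": GLCM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "ngtdm": NGTDM_NAMES,
    "gldm": GLDM_NAMES,
}

FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{family}_{name}" for family, names in FAMILY_NAMES.items() for name in names
)
FEATURE_FAMILIES: tuple[str, ...] = tuple(
    family for family, names in FAMILY_NAMES.items() for _ in names
)

N_FEATURES = len(FEATURE_NAMES)
assert N_FEATURES == 104


@lru_cache(maxsize=16)
def _full_rect_shape(shape: tuple[int, int], pixel_spacing: float) -> dict[str, float]:
    return shape2d(np.ones(shape, dtype=bool), pixel_spacing=pixel_spacing)


@dataclass(frozen=True)
class FeatureVector:
    """The 104 named texture features of one ROI, in canonical order."""

    values: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES
    families: tuple[str, ...] = FEATURE_FAMILIES

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ValueError("feature vector length mismatch")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


def extract_all(
    patch: np.ndarray,
    n_bins: int = 32,
    pixel_spacing: float = 1.0,
    mask: np.ndarray | None = None,
) -> FeatureVector:
    """Compute the full 104-feature battery for one grayscale patch.

    Parameters
    ----------
    patch:
        2-D grayscale image patch (the pipeline uses 64x64 8-bit ROIs).
    n_bins:
        Gray-level count for quantization (fixed bin count).
    pixel_spacing:
        mm per pixel; affects TotalEnergy and the shape features.
    mask:
        Optional region mask for the shape family; defaults to the full
        rectangle (the pipeline's square ROI).
    """
    patch = np.asarray(patch)
    if patch.ndim != 2 or patch.size == 0:
        raise ValueError("patch must be a non-empty 2-D array")
    if mask is None:
        # the full-rectangle mask repeats for every ROI of one geometry;
        # its shape features depend only on (shape, spacing)
        shape_feats = _full_rect_shape(patch.shape, pixel_spacing)
    else:
        shape_feats = shape2d(mask, pixel_spacing=pixel_spacing)
    q = quantize(patch, n_bins=n_bins)
    parts = (
        first_order(patch, n_bins=n_bins, pixel_spacing=pixel_spacing),
        shape_feats,
        glcm_features(q),
        glrlm_features(q),
        glszm_features(q),
        ngtdm_features(q),
        gldm_features(q),
    )
    values = np.array(
        [d[name] for d, names in zip(parts, FAMILY_NAMES.values()) for name in names],
        dtype=np.float64,
    )
    return FeatureVector(values=values)


def extract_matrix(
    patches, n_bins: int = 32, pixel_spacing: float = 1.0
) -> np.ndarray:
    """Feature matrix (n_patches x 104) for an iterable of patches."""
    return np.array(
        [extract_all(p, n_bins=n_bins, pixel_spacing=pixel_spacing).values for p in patches]
    )


__all__ = [
    "FAMILY_NAMES",
    "FEATURE_NAMES",
    "FEATURE_FAMILIES",
    "N_FEATURES",
    "FeatureVector",
    "NormalizationStats",
    "QuantizedPatch",
    "apply_normalizer",
    "extract_all",
    "extract_matrix",
    "first_order",
    "fit_normalizer",
    "gldm_features",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
    "quantize",
    "shape2d",
]
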