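"""Z-score normalization fitted on the training split only."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_STD_FLOOR = 1e-12


@dataclass(frozen=True)
class NormalizationStats:
    """Per-feature mean and standard deviation (floored at ``_STD_FLOOR``)."""

    mean: np.ndarray
    std: np.ndarray
    feature_names: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "std": self.std.tolist(),
            "feature_names": list(self.feature_names),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationStats":
        return cls(
            mean=np.asarray(d["mean"], dtype=np.float64),
            std=np.asarray(d["std"], dtype=np.float64),
            feature_names=tuple(d["feature_names"]),
        )


def fit_normalizer(
    vectors: np.ndarray, feature_names: tuple[str, ...]
) -> NormalizationStats:
    """Estimate per-feature mean/std from training-set ``vectors`` (n x p)."""
    vectors = np.atleast_2d(np.asarray(vectors, dtype=np.float64))
    if vectors.shape[0] < 2:
        raise ValueError("need at least 2 training vectors")
    std = vectors.std(axis=0)
    return NormalizationStats(
        mean=vectors.mean(axis=0),
        std=np.maximum(std, _STD_FLOOR),
        feature_names=tuple(feature_names),
    )


def apply_normalizer(stats: NormalizationStats, vectors: np.ndarray) -> np.ndarray:
    """Z-score ``vectors`` (1-D or n x p) with training statistics.

    A feature that was constant in training maps to 0 for the training value
    (its std is floored, and deviations are measured from the training mean).
    """
    vectors = np.asarray(vectors, dtype=np.float64)
    return (vectors - stats.mean) / stats.std
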