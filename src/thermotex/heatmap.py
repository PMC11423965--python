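"""Per-pixel temperature maps, lethal-isotherm segmentation and area metrics.

The heat map slides the trained model's 64x64 feature window over a target
region (reflect-padded at frame borders) and predicts a temperature for
every output pixel.  The area where the prediction reaches the 54 C lethal
isotherm is the machine-learning coagulation-zone estimate S_p; it is
compared with the gold-standard area S_r and with the sonographer's
hyperechoic-ellipse area S_v = (1/2) * a * b * pi (a = major diameter,
b = half the minor diameter) through the error ratio ER = |x - S_r| / S_r.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .features import extract_all
from .model import TrainedTemperatureModel, predict

LETHAL_ISOTHERM_C = 54.0


@dataclass(frozen=True)
class HeatMap:
    """Predicted temperatures (C) over a region of the frame."""

    values: np.ndarray
    origin_xy: tuple[int, int]  # top-left of the region in frame coordinates
    mm_per_px: float


@dataclass(frozen=True)
class EllipseMeasure:
    """Hyperechoic ellipse calipers: major diameter a, half minor diameter b (mm)."""

    a_mm: float
    b_mm: float

    def __post_init__(self) -> None:
        if self.a_mm <= 0 or self.b_mm <= 0:
            raise ValueError("ellipse diameters must be positive")


@dataclass(frozen=True)
class AreaReport:
    case_id: str
    S_r_mm2: float
    S_v_mm2: float
    S_p_mm2: float
    ER_hyper: float
    ER_ml: float


def predict_heatmap(
    frame: np.ndarray,
    model: TrainedTemperatureModel,
    region: tuple[int, int, int, int],
    mm_per_px: float,
    window: int = 64,
    stride: int = 1,
    n_bins: int = 32,
) -> HeatMap:
    """Sliding-window temperature prediction over ``region`` = (x0, y0, x1, y1).

    Each output pixel's 64x64 window is centred on it (reflect padding at the
    frame edge), featurized, normalized with the model's training statistics
    and passed through the forest.  ``stride > 1`` predicts a coarse grid and
    upsamples nearest-neighbour to full region resolution.
    """
    x0, y0, x1, y1 = region
    h, w = frame.shape
    if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
        raise ValueError(f"region {region} outside frame {frame.shape}")
    half = window // 2
    padded = np.pad(frame.astype(np.float64), half, mode="reflect")
    ys = np.arange(y0, y1, stride)
    xs = np.arange(x0, x1, stride)
    feats = np.empty((len(ys) * len(xs), 104))
    k = 0
    for y in ys:
        for x in xs:
            patch = padded[y : y + window, x : x + window]
            feats[k] = extract_all(patch, n_bins=n_bins, pixel_spacing=mm_per_px).values
            k += 1
    temps = predict(model, feats).reshape(len(ys), len(xs))
    if stride > 1:
        temps = np.repeat(np.repeat(temps, stride, axis=0), stride, axis=1)
        temps = temps[: y1 - y0, : x1 - x0]
    return HeatMap(values=temps, origin_xy=(x0, y0), mm_per_px=mm_per_px)


def threshold_area(
    heat_map: HeatMap,
    threshold_C: float = LETHAL_ISOTHERM_C,
    largest_component: bool = False,
) -> float:
    """Area (mm^2) of pixels predicted at or above ``threshold_C``.

    By default every supra-threshold pixel counts, including spurious hot
    spots away from the ablation centre (the behaviour the evaluation
    metric assumes); ``largest_component=True`` keeps only the largest
    8-connected component.
    """
    mask = heat_map.values >= threshold_C
    if largest_component and mask.any():
        labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
        sizes = np.bincount(labels.ravel())[1:]
        mask = labels == (int(np.argmax(sizes)) + 1)
    return float(np.count_nonzero(mask)) * heat_map.mm_per_px**2


def ellipse_area(measure: EllipseMeasure) -> float:
    """Hyperechoic area S_v = (1/2) * a * b * pi (mm^2)."""
    return 0.5 * measure.a_mm * measure.b_mm * math.pi


def error_ratio(x_mm2: float, S_r_mm2: float) -> float:
    """ER = |x - S_r| / S_r; 0 means a perfect area estimate."""
    if S_r_mm2 <= 0:
        raise ValueError("gold-standard area must be positive")
    return abs(x_mm2 - S_r_mm2) / S_r_mm2


def case_report(
    case_id: str,
    S_r_mm2: float,
    hyperechoic,
    ml_area_mm2: float | None = None,
    heat_map: HeatMap | None = None,
    threshold_C: float = LETHAL_ISOTHERM_C,
) -> AreaReport:
    """Per-case area comparison.

    ``hyperechoic`` is either an :class:`EllipseMeasure` (calipers) or a
    pre-measured S_v in mm^2; the ML area comes from ``ml_area_mm2`` or is
    computed by thresholding ``heat_map``.
    """
    S_v = ellipse_area(hyperechoic) if isinstance(hyperechoic, EllipseMeasure) else float(hyperechoic)
    if ml_area_mm2 is None:
        if heat_map is None:
            raise ValueError("provide ml_area_mm2 or a heat_map")
        ml_area_mm2 = threshold_area(heat_map, threshold_C=threshold_C)
    return AreaReport(
        case_id=case_id,
        S_r_mm2=S_r_mm2,
        S_v_mm2=S_v,
        S_p_mm2=float(ml_area_mm2),
        ER_hyper=error_ratio(S_v, S_r_mm2),
        ER_ml=error_ratio(float(ml_area_mm2), S_r_mm2),
    )


def group_summary(reports) -> dict[str, float]:
    """Arithmetic group means of the per-case error ratios."""
    reports = list(reports)
    if not reports:
        raise ValueError("no reports")
    return {
        "mean_ER_hyper": float(np.mean([r.ER_hyper for r in reports])),
        "mean_ER_ml": float(np.mean([r.ER_ml for r in reports])),
        "n_cases": len(reports),
    }
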