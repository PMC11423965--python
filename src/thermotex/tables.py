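"""Published per-case coagulation-area measurements (the evaluation input).

Five representative cases per power group, each with the gold-standard
coagulation area S_r (ImageJ tracing of the sectioned specimen), the
sonographer's hyperechoic-ellipse area S_v, and the machine-learning
isotherm area S_p, all in mm^2.  Error ratios are *not* stored — they are
recomputed from these areas by :func:`thermotex.heatmap.error_ratio`.
"""

from __future__ import annotations

import pandas as pd

_COLUMNS = ("gold_mm2", "hyperechoic_mm2", "ml_mm2")

_AREAS_15W = (
    (192.969, 258.423, 133.690),
    (153.100, 221.558, 146.042),
    (176.083, 233.870, 144.782),
    (152.061, 218.191, 178.112),
    (169.047, 246.556, 153.136),
)

_AREAS_20W = (
    (193.357, 236.522, 188.719),
    (261.281, 308.494, 205.808),
    (256.924, 301.556, 207.278),
    (241.527, 281.911, 217.388),
    (264.442, 307.946, 242.652),
)


def coagulation_area_table(power: str) -> pd.DataFrame:
    """The measured-area table for power group ``"P15"`` or ``"P20"``."""
    try:
        rows = {"P15": _AREAS_15W, "P20": _AREAS_20W}[power]
    except KeyError:
        raise ValueError(f"unknown power group {power!r}") from None
    return pd.DataFrame(rows, columns=list(_COLUMNS))


def area_error_ratios(table: pd.DataFrame) -> pd.DataFrame:
    """Per-case ER columns for a gold/hyperechoic/ml area table."""
    from .heatmap import error_ratio

    out = table.copy()
    out["ER_hyper"] = [
        error_ratio(v, g) for v, g in zip(table["hyperechoic_mm2"], table["gold_mm2"])
    ]
    out["ER_ml"] = [
        error_ratio(p, g) for p, g in zip(table["ml_mm2"], table["gold_mm2"])
    ]
    return out
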