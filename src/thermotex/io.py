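"""On-disk case layout.

A case directory holds::

    frames/frame_00000.png ...   8-bit grayscale frames (ablation clock)
    frames.csv                   frame_index, time_s
    probes.csv                   time_s, ch101..ch107 (thermometer clock, C)
    markup.yaml                  probe pixel coords, needle axis, mm_per_px
    truth.json                   isotherm area, hyperechoic (a, b)   [synthetic]
    truth_field.tif              final temperature field x 100, 16-bit [synthetic]

Real exported data in the same shape (frames + frames.csv + probes.csv +
markup.yaml) can be dropped in; the truth files exist only for synthetic
cases.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .ingest import DEFAULT_CHANNELS, FrameSequence, TemperatureLog

TEMP_TIFF_SCALE = 100.0  # truth_field.tif stores degrees C x 100


def write_case(case, out_dir) -> Path:
    """Write a SyntheticCase to ``out_dir`` in the standard layout."""
    out = Path(out_dir)
    (out / "frames").mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(case.frames):
        iio.imwrite(out / "frames" / f"frame_{i:05d}.png", frame)
    pd.DataFrame(
        {"frame_index": np.arange(len(case.frames)), "time_s": case.frame_times_s}
    ).to_csv(out / "frames.csv", index=False)
    probes = pd.DataFrame({"time_s": case.probe_times_s})
    for ch, series in zip(DEFAULT_CHANNELS, case.probe_values_C):
        probes[f"ch{ch}"] = series
    probes.to_csv(out / "probes.csv", index=False)
    markup = {
        "case_id": case.case_id,
        "mm_per_px": float(case.cfg.mm_per_px),
        "probe_points": [[int(x), int(y)] for x, y in case.cfg.probe_points],
        "needle_axis": [[float(c) for c in p] for p in case.cfg.needle_axis],
        "channel_map": {int(ch): i + 1 for i, ch in enumerate(DEFAULT_CHANNELS)},
        "preheat_s": float(case.cfg.preheat_s),
        "duration_s": float(case.cfg.duration_s),
        "frame_rate_fps": float(case.cfg.frame_rate_fps),
    }
    (out / "markup.yaml").write_text(yaml.safe_dump(markup, sort_keys=False))
    truth = {
        "isotherm_area_mm2": case.truth_isotherm_area_mm2,
        "hyperechoic_a_mm": case.truth_hyperechoic[0],
        "hyperechoic_b_mm": case.truth_hyperechoic[1],
        "power_preset": case.cfg.power_preset,
        "rng_seed": int(case.cfg.rng_seed),
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
    tifffile.imwrite(
        out / "truth_field.tif",
        np.round(case.final_field.values * TEMP_TIFF_SCALE).astype(np.uint16),
    )
    return out


def read_markup(case_dir) -> dict:
    return yaml.safe_load((Path(case_dir) / "markup.yaml").read_text())


def read_frames(case_dir) -> FrameSequence:
    case_dir = Path(case_dir)
    manifest = pd.read_csv(case_dir / "frames.csv")
    frames = np.stack(
        [
            iio.imread(case_dir / "frames" / f"frame_{i:05d}.png")
            for i in manifest["frame_index"]
        ]
    )
    return FrameSequence(frames=frames, times_s=manifest["time_s"].to_numpy())


def read_probe_log(case_dir) -> TemperatureLog:
    df = pd.read_csv(Path(case_dir) / "probes.csv")
    channels = tuple(int(c[2:]) for c in df.columns if c.startswith("ch"))
    return TemperatureLog(
        channel_ids=channels,
        times_s=df["time_s"].to_numpy(),
        values_C=np.stack([df[f"ch{c}"].to_numpy() for c in channels]),
    )


def read_truth(case_dir) -> dict:
    return json.loads((Path(case_dir) / "truth.json").read_text())
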