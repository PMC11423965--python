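"""Ingest simulated cases into temperature-ROI pairs and featurize them.

Reads the case directories written by 01_simulate_cases.py, cuts 64x64 ROIs
at the marked probe points of every keyframe, computes the 104-feature
battery, and writes one feature table per power group to scratch/ (they are
a few MB) plus a compact per-probe summary to results/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from thermotex.features import FEATURE_NAMES, extract_matrix
from thermotex.ingest import (
    FrameSequence,
    extract_keyframes,
    pair_samples,
    split_dataset,
    trim_preheat,
)
from thermotex import io as tio

ROOT = Path(__file__).resolve().parents[1]


def featurize_case(case_dir: Path, split_seed: int) -> pd.DataFrame:
    markup = tio.read_markup(case_dir)
    log = trim_preheat(
        tio.read_probe_log(case_dir),
        start_s=markup["preheat_s"],
        end_s=markup["preheat_s"] + markup["duration_s"],
    )
    keyframes = extract_keyframes(
        tio.read_frames(case_dir), fps=int(round(markup["frame_rate_fps"]))
    )
    samples = pair_samples(
        keyframes, log, markup["probe_points"], case_id=markup["case_id"]
    )
    ds = split_dataset(samples, seed=split_seed)
    X = extract_matrix(
        [s.patch for s in ds.samples], pixel_spacing=markup["mm_per_px"]
    )
    meta = pd.DataFrame(
        {
            "case_id": [s.case_id for s in ds.samples],
            "point_index": [s.point_index for s in ds.samples],
            "time_s": [s.time_s for s in ds.samples],
            "temperature_C": [s.temperature_C for s in ds.samples],
            "split": list(ds.split_labels),
        }
    )
    return pd.concat([meta, pd.DataFrame(X, columns=FEATURE_NAMES)], axis=1)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cases", type=Path, default=ROOT / "scratch" / "cases")
    ap.add_argument("--split-seed", type=int, default=0)
    args = ap.parse_args()

    index = pd.read_csv(ROOT / "results" / "simulated_cases.csv")
    summaries = []
    for power, group in index.groupby("power"):
        tables = [
            featurize_case(args.cases / cid, args.split_seed)
            for cid in group["case_id"]
        ]
        table = pd.concat(tables, ignore_index=True)
        out = ROOT / "scratch" / f"features_{power.lower()}.csv"
        table.to_csv(out, index=False)
        print(f"{power}: {len(table)} samples x {len(FEATURE_NAMES)} features -> {out}")
        s = (
            table.groupby("point_index")["temperature_C"]
            .agg(["min", "max", "mean"])
            .round(1)
            .reset_index()
        )
        s.insert(0, "power", power)
        summaries.append(s)
    summary = pd.concat(summaries, ignore_index=True)
    summary.to_csv(ROOT / "results" / "probe_temperature_summary.csv", index=False)
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
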