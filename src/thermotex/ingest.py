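"""From raw case data to temperature-ROI sample pairs.

The acquisition protocol this stage assumes: the thermometer starts first;
ablation (and video recording) starts 15 s later; the thermometer samples 7
channels at 2 Hz for the 180 s ablation.  Synchronization therefore means
(1) trimming the temperature log to the ablation window and re-zeroing its
clock, (2) thinning the 12 fps video to 2 frames/s by keeping the first and
sixth frame of each second, and (3) pairing each kept frame with the
nearest-in-time reading of each channel.

Coordinates are 0-based pixels, (x=column, y=row), origin top-left.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

PAIRING_TOLERANCE_S = 0.25  # half the 2 Hz sampling period
DEFAULT_CHANNELS = tuple(range(101, 108))  # channel 101 -> point 1, ...


@dataclass(frozen=True)
class TemperatureLog:
    """Multi-channel thermocouple series on a common clock."""

    channel_ids: tuple[int, ...]
    times_s: np.ndarray
    values_C: np.ndarray  # (n_channels, n_times)

    def __post_init__(self) -> None:
        if self.values_C.shape != (len(self.channel_ids), len(self.times_s)):
            raise ValueError("log shape mismatch")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("log timestamps must be strictly increasing")


@dataclass(frozen=True)
class FrameSequence:
    """Timestamped 8-bit grayscale frames (all the same shape)."""

    frames: np.ndarray  # (n, H, W) uint8
    times_s: np.ndarray

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.times_s):
            raise ValueError("frame/timestamp count mismatch")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("frame timestamps must be strictly increasing")


@dataclass(frozen=True)
class RoiSample:
    """One 64x64 patch paired with one thermocouple reading."""

    patch: np.ndarray
    point_index: int  # 1..7
    time_s: float
    temperature_C: float
    case_id: str


@dataclass(frozen=True)
class Dataset:
    samples: tuple[RoiSample, ...]
    split_labels: tuple[str, ...]
    split_seed: int

    def subset(self, split: str) -> list[RoiSample]:
        return [s for s, l in zip(self.samples, self.split_labels) if l == split]


class CoverageError(ValueError):
    """The temperature log does not cover the requested window."""


class PairingError(ValueError):
    """A keyframe has no temperature reading within tolerance."""


def trim_preheat(
    log: TemperatureLog, start_s: float = 15.0, end_s: float = 195.0
) -> TemperatureLog:
    """Keep readings with ``start_s <= t < end_s`` and re-zero the clock.

    At 2 Hz over the standard [15, 195) ablation window this retains exactly
    360 readings per channel.
    """
    t = log.times_s
    dt = float(np.median(np.diff(t)))
    # the window is half-open, so the last required reading is at end_s - dt
    if t[0] > start_s + 1e-9 or t[-1] < end_s - dt - 1e-9:
        missing = (
            f"[{max(t[-1] + dt, start_s):g}, {end_s:g})"
            if t[-1] < end_s - dt
            else f"[{start_s:g}, {t[0]:g})"
        )
        raise CoverageError(
            f"log covers [{t[0]:g}, {t[-1]:g}] but the ablation window needs "
            f"[{start_s:g}, {end_s:g}); missing {missing}"
        )
    keep = (t >= start_s) & (t < end_s)
    return TemperatureLog(
        channel_ids=log.channel_ids,
        times_s=t[keep] - start_s,
        values_C=log.values_C[:, keep],
    )


def extract_keyframes(seq: FrameSequence, fps: int) -> FrameSequence:
    """Keep the first and sixth frame of each whole second.

    ``fps`` is the nominal video rate (>= 6).  A second with fewer than 6
    frames contributes only what it has, with a warning.  Output rate is 2
    frames/s, but spacing is 5/12 s then 7/12 s at 12 fps — pairing is by
    nearest timestamp downstream, not by assuming uniform spacing.
    """
    if fps < 6:
        raise ValueError("frame rate must be at least 6 fps")
    seconds = np.floor(seq.times_s + 1e-9).astype(np.int64)
    within = np.rint((seq.times_s - seconds) * fps).astype(np.int64)
    keep = (within == 0) | (within == 5)
    for sec in np.unique(seconds):
        if np.count_nonzero(seconds == sec) < 6:
            logger.warning("second %d has fewer than 6 frames", sec)
    return FrameSequence(frames=seq.frames[keep], times_s=seq.times_s[keep])


def cut_roi(frame: np.ndarray, center_xy: tuple[int, int], size: int = 64) -> np.ndarray:
    """The ``size`` x ``size`` window around ``center_xy``.

    Even-size windows cannot be symmetric about one pixel; the convention is
    the half-open span ``[c - size//2, c + (size+1)//2)`` on each axis.  A
    window that would leave the frame raises (no padding for training ROIs).
    """
    x, y = center_xy
    half = size // 2
    y0, y1 = y - half, y - half + size
    x0, x1 = x - half, x - half + size
    h, w = frame.shape
    if y0 < 0 or x0 < 0 or y1 > h or x1 > w:
        raise ValueError(
            f"ROI [{y0}:{y1}, {x0}:{x1}] exceeds frame bounds {frame.shape}"
        )
    return frame[y0:y1, x0:x1]


def pair_samples(
    keyframes: FrameSequence,
    log: TemperatureLog,
    probe_points,
    case_id: str = "case",
    roi_size: int = 64,
    tolerance_s: float = PAIRING_TOLERANCE_S,
) -> list[RoiSample]:
    """Pair every keyframe x probe point with the nearest temperature reading.

    360 keyframes x 7 points -> 2520 samples per standard case.
    """
    samples: list[RoiSample] = []
    orphans = []
    idx = np.searchsorted(log.times_s, keyframes.times_s)
    for k, t in enumerate(keyframes.times_s):
        cands = [i for i in (idx[k] - 1, idx[k]) if 0 <= i < len(log.times_s)]
        best = min(cands, key=lambda i: abs(log.times_s[i] - t))
        if abs(log.times_s[best] - t) > tolerance_s:
            orphans.append(float(t))
            continue
        for p, (x, y) in enumerate(probe_points, start=1):
            samples.append(
                RoiSample(
                    patch=cut_roi(keyframes.frames[k], (x, y), size=roi_size),
                    point_index=p,
                    time_s=float(t),
                    temperature_C=float(log.values_C[p - 1, best]),
                    case_id=case_id,
                )
            )
    if orphans:
        raise PairingError(
            f"{len(orphans)} keyframes have no temperature reading within "
            f"{tolerance_s} s: {orphans[:5]}..."
        )
    return samples


def split_dataset(
    samples,
    ratio: tuple[int, int, int] = (4, 1, 1),
    seed: int = 0,
    grouping: str = "per_sample",
) -> Dataset:
    """Random train/val/test split in the given ratio (default 4:1:1).

    ``per_sample`` shuffles all samples independently (the protocol's
    literal procedure); ``per_case`` keeps whole cases together, which is
    the honest choice when samples from one ablation are highly correlated.
    Split sizes follow largest-remainder rounding (within +/-1 of exact).
    """
    samples = list(samples)
    if len(samples) < sum(ratio):
        raise ValueError(f"need at least {sum(ratio)} samples")
    rng = np.random.default_rng(seed)
    names = ("train", "val", "test")

    def _sizes(n: int) -> list[int]:
        total = sum(ratio)
        exact = [n * r / total for r in ratio]
        base = [int(np.floor(e)) for e in exact]
        rem = n - sum(base)
        order = np.argsort([b - e for b, e in zip(base, exact)])
        for i in range(rem):
            base[order[i]] += 1
        return base

    labels = np.empty(len(samples), dtype=object)
    if grouping == "per_sample":
        perm = rng.permutation(len(samples))
        sizes = _sizes(len(samples))
        stop = np.cumsum(sizes)
        labels[perm[: stop[0]]] = "train"
        labels[perm[stop[0] : stop[1]]] = "val"
        labels[perm[stop[1] :]] = "test"
    elif grouping == "per_case":
        cases = sorted({s.case_id for s in samples})
        perm = rng.permutation(len(cases))
        sizes = _sizes(len(cases))
        stop = np.cumsum(sizes)
        assignment = {}
        for rank, ci in enumerate(perm):
            assignment[cases[ci]] = names[int(np.searchsorted(stop, rank, side="right"))]
        for i, s in enumerate(samples):
            labels[i] = assignment[s.case_id]
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    return Dataset(samples=tuple(samples), split_labels=tuple(labels), split_seed=seed)


def case_to_samples(case, roi_size: int = 64) -> list[RoiSample]:
    """Run the full ingest chain on a SyntheticCase (or equivalent)."""
    cfg = case.cfg
    log = TemperatureLog(
        channel_ids=DEFAULT_CHANNELS,
        times_s=case.probe_times_s,
        values_C=case.probe_values_C,
    )
    trimmed = trim_preheat(
        log, start_s=cfg.preheat_s, end_s=cfg.preheat_s + cfg.duration_s
    )
    seq = FrameSequence(frames=case.frames, times_s=case.frame_times_s)
    keyframes = extract_keyframes(seq, fps=int(round(cfg.frame_rate_fps)))
    return pair_samples(
        keyframes, trimmed, cfg.probe_points, case_id=case.case_id, roi_size=roi_size
    )
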