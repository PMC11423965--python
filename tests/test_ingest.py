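"""Tests for log trimming, keyframe extraction, ROI cutting and splitting."""

import numpy as np
import pytest

from conftest import micro_config
from thermotex.ingest import (
    CoverageError,
    DEFAULT_CHANNELS,
    Dataset,
    FrameSequence,
    PairingError,
    RoiSample,
    TemperatureLog,
    case_to_samples,
    cut_roi,
    extract_keyframes,
    pair_samples,
    split_dataset,
    trim_preheat,
)


def _log(t_end=200.0, rate=2.0, t0=0.0):
    times = np.arange(t0, t_end, 1.0 / rate)
    values = np.tile(37.0 + times * 0.1, (7, 1))
    return TemperatureLog(channel_ids=DEFAULT_CHANNELS, times_s=times, values_C=values)


def _frames(n, h=8, w=8, fps=12):
    return FrameSequence(
        frames=np.zeros((n, h, w), dtype=np.uint8), times_s=np.arange(n) / fps
    )


class TestTrim:
    def test_standard_window_keeps_360_readings(self):
        trimmed = trim_preheat(_log(200.0))
        assert trimmed.values_C.shape == (7, 360)
        assert trimmed.times_s[0] == 0.0
        assert trimmed.times_s[-1] == pytest.approx(179.5)

    def test_exact_window_is_identity_rezeroed(self):
        log = _log(t0=15.0, t_end=195.0)
        trimmed = trim_preheat(log)
        assert np.allclose(trimmed.values_C, log.values_C)
        assert np.allclose(trimmed.times_s, log.times_s - 15.0)

    def test_short_log_raises_coverage_error(self):
        with pytest.raises(CoverageError, match="missing"):
            trim_preheat(_log(100.0))


class TestKeyframes:
    def test_standard_video_yields_360_keyframes(self):
        out = extract_keyframes(_frames(2160), fps=12)
        assert len(out.frames) == 360

    def test_one_second_keeps_first_and_sixth(self):
        seq = _frames(12)
        out = extract_keyframes(seq, fps=12)
        assert np.allclose(out.times_s, [0.0, 5 / 12])

    def test_six_fps_two_seconds(self):
        out = extract_keyframes(_frames(12, fps=6), fps=6)
        assert len(out.frames) == 4
        assert np.allclose(out.times_s, [0.0, 5 / 6, 1.0, 1.0 + 5 / 6])

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError):
            extract_keyframes(_frames(10, fps=5), fps=5)


class TestCutRoi:
    def test_half_open_window_convention(self):
        frame = np.arange(128 * 128).reshape(128, 128)
        patch = cut_roi(frame, (64, 64), size=64)
        assert patch.shape == (64, 64)
        assert np.array_equal(patch, frame[32:96, 32:96])

    def test_out_of_bounds_raises(self):
        with pytest.raises(ValueError, match="exceeds frame bounds"):
            cut_roi(np.zeros((128, 128)), (10, 10), size=64)

    def test_constant_frame_gives_constant_patch(self):
        patch = cut_roi(np.full((128, 128), 9), (64, 64))
        assert np.all(patch == 9)

    def test_translation_consistency(self, rng):
        frame = rng.integers(0, 256, (100, 100))
        shifted = np.roll(np.roll(frame, 3, axis=0), 5, axis=1)
        a = cut_roi(frame, (50, 50), size=16)
        b = cut_roi(shifted, (55, 53), size=16)
        assert np.array_equal(a, b)


class TestPairing:
    def test_single_keyframe_single_point(self):
        log = trim_preheat(_log())
        seq = FrameSequence(
            frames=np.zeros((1, 64, 64), dtype=np.uint8), times_s=np.array([0.4])
        )
        samples = pair_samples(seq, log, [(32, 32)], roi_size=32)
        assert len(samples) == 1
        # nearest reading to 0.4 s is the one at 0.5 s
        assert samples[0].temperature_C == pytest.approx(log.values_C[0, 1])

    def test_offset_beyond_tolerance_raises(self):
        log = trim_preheat(_log())
        seq = FrameSequence(
            frames=np.zeros((1, 64, 64), dtype=np.uint8), times_s=np.array([0.26])
        )
        with pytest.raises(PairingError):
            pair_samples(seq, log, [(32, 32)], roi_size=32, tolerance_s=0.01)


class TestSplit:
    @staticmethod
    def _dummy_samples(n, case_ids=None):
        patch = np.zeros((2, 2), dtype=np.uint8)
        return [
            RoiSample(
                patch=patch,
                point_index=1,
                time_s=float(i),
                temperature_C=37.0,
                case_id=(case_ids[i] if case_ids else "c"),
            )
            for i in range(n)
        ]

    def test_standard_ratio_counts(self):
        ds = split_dataset(self._dummy_samples(2520), seed=0)
        counts = {s: ds.split_labels.count(s) for s in ("train", "val", "test")}
        assert counts == {"train": 1680, "val": 420, "test": 420}

    def test_deterministic_for_fixed_seed(self):
        samples = self._dummy_samples(100)
        assert (
            split_dataset(samples, seed=5).split_labels
            == split_dataset(samples, seed=5).split_labels
        )

    def test_minimal_six_samples(self):
        ds = split_dataset(self._dummy_samples(6), seed=0)
        counts = {s: ds.split_labels.count(s) for s in ("train", "val", "test")}
        assert counts == {"train": 4, "val": 1, "test": 1}

    def test_per_case_grouping_keeps_cases_whole(self):
        ids = [f"case{i % 6}" for i in range(120)]
        ds = split_dataset(self._dummy_samples(120, ids), seed=1, grouping="per_case")
        for cid in set(ids):
            labels = {
                l for s, l in zip(ds.samples, ds.split_labels) if s.case_id == cid
            }
            assert len(labels) == 1

    def test_every_sample_in_exactly_one_split(self):
        ds = split_dataset(self._dummy_samples(100), seed=2)
        assert len(ds.split_labels) == 100
        assert set(ds.split_labels) == {"train", "val", "test"}


class TestRoundTrip:
    def test_short_case_sample_count_and_temperature_fidelity(self):
        """generate -> ingest yields floor(duration)*2*7 samples whose
        temperatures track the ground-truth field within probe noise."""
        from thermotex.sim import field_values_at, generate_case

        cfg = micro_config(duration_s=20.0)
        case = generate_case(cfg)
        samples = case_to_samples(case, roi_size=24)
        assert len(samples) == 20 * 2 * 7

        errors = []
        for s in samples:
            x, y = cfg.probe_points[s.point_index - 1]
            truth = field_values_at(cfg, s.time_s, [(x, y)])[0]
            errors.append(abs(s.temperature_C - truth))
        # nearest-reading pairing adds <=1/12 s of clock skew on top of the
        # 0.3 C sensor noise; 99% of samples stay within 3 sigma + skew
        frac_ok = np.mean(np.array(errors) <= 3 * cfg.probe_noise_C + 0.3)
        assert frac_ok >= 0.99
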