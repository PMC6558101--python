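"""Sample-entropy computation, activity profiling, segment extraction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from emgmotion import (
    ActivityProfile,
    Recording,
    SampEnParams,
    extract_segments,
    generate_trial,
    preprocess_pipeline,
    sample_entropy,
    sampen_profile,
    segment_recording,
    sum_channels,
    threshold_activity,
)
from emgmotion.exceptions import DomainError
from emgmotion.segmentation import sampen_cap

from conftest import interval_iou, sampen_bruteforce


class TestSumChannels:
    def test_two_channel_example(self):
        rec = Recording(np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert np.array_equal(sum_channels(rec, [0, 1]), [3.0, 7.0])

    def test_single_channel_is_identity(self):
        rec = Recording(np.arange(10.0)[:, None])
        assert np.array_equal(sum_channels(rec, [0]), np.arange(10.0))

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(5)
        rec = Recording(rng.standard_normal((200, 8)))
        summed = sum_channels(rec)
        oracle = np.array(
            [sum(rec.data[t, c] for c in range(8)) for t in range(200)]
        )
        assert np.array_equal(summed, oracle)

    def test_estop_channel_in_sum_warns(self):
        rec = Recording(np.zeros((10, 9)), estop_channel=8)
        with pytest.warns(UserWarning, match="emergency-stop"):
            sum_channels(rec, list(range(9)))

    def test_empty_channel_list_rejected(self):
        rec = Recording(np.zeros((10, 2)))
        with pytest.raises(DomainError):
            sum_channels(rec, [])


class TestSampleEntropy:
    def test_constant_window_is_perfectly_regular(self):
        for c in (0.0, 3.5, -2.0):
            assert sample_entropy(np.full(50, c), m=2, r=0.1) == 0.0

    def test_matches_bruteforce_on_small_pattern(self):
        x = np.array([1, 2, 3, 2, 1, 2, 3, 2, 1, 2], dtype=float)
        expected = sampen_bruteforce(x, m=2, r=0.5)
        assert sample_entropy(x, m=2, r=0.5) == expected

    def test_white_noise_more_irregular_than_sine(self):
        rng = np.random.default_rng(11)
        noise = rng.standard_normal(128)
        t = np.arange(128) / 1000.0
        sine = np.sin(2 * np.pi * 5 * t)
        sine = (sine - sine.mean()) / sine.std() * noise.std()
        r = 0.25 * noise.std()
        assert sample_entropy(noise, 2, r) > sample_entropy(sine, 2, r)

    def test_no_matches_hits_documented_cap(self):
        x = np.geomspace(1.0, 1e6, 20)  # exploding spacing: nothing matches
        assert sample_entropy(x, m=2, r=1e-9) == sampen_cap(20, 2)

    def test_window_too_short_rejected(self):
        with pytest.raises(DomainError):
            sample_entropy(np.zeros(3), m=2, r=0.1)

    def test_nonincreasing_in_tolerance(self):
        for seed in (1, 2, 3):
            x = np.random.default_rng(seed).standard_normal(150)
            grid = np.linspace(0.05, 2.0, 12) * x.std()
            values = [sample_entropy(x, 2, r) for r in grid]
            assert all(b <= a + 1e-12 for a, b in zip(values, values[1:]))

    @given(st.integers(min_value=0, max_value=10_000))
    def test_agrees_with_bruteforce_on_random_windows(self, seed):
        rng = np.random.default_rng(seed)
        length = int(rng.integers(10, 60))
        x = rng.standard_normal(length)
        r = float(rng.uniform(0.05, 0.5)) * float(x.std())
        assert sample_entropy(x, 2, r) == sampen_bruteforce(x, 2, r)


class TestProfile:
    def test_rest_only_trial_is_fully_inactive(self, synth_config):
        trial = generate_trial(synth_config, "rest", 2)
        proc = preprocess_pipeline(trial.recording)
        profile = threshold_activity(sampen_profile(sum_channels(proc), proc.fs))
        assert (profile.sampen < profile.params.d).all()
        assert not profile.s.any()

    def test_window_count_arithmetic(self):
        x = np.random.default_rng(0).standard_normal(1000)
        profile = sampen_profile(x, fs=1000.0)
        assert len(profile.sampen) == (1000 - 128) // 64 + 1 == 14
        assert np.array_equal(profile.window_starts, np.arange(14) * 64)

    def test_burst_active_rest_flanks_inactive(self, synth_config):
        trial = generate_trial(synth_config, "shoulder_abduction", 6)
        proc = preprocess_pipeline(trial.recording)
        profile = threshold_activity(sampen_profile(sum_channels(proc), proc.fs))
        start, end = trial.true_burst
        starts = profile.window_starts
        inside = (starts >= start) & (starts + profile.window_len <= end)
        outside = (starts + profile.window_len <= start) | (starts >= end)
        assert profile.s[inside].any()
        assert not profile.s[outside].any()

    def test_profile_invariant_under_positive_rescaling(self, synth_config):
        trial = generate_trial(synth_config, "elbow_flexion", 13)
        proc = preprocess_pipeline(trial.recording)
        x = sum_channels(proc)
        a = sampen_profile(x, proc.fs)
        b = sampen_profile(1000.0 * x, proc.fs)
        assert np.allclose(a.sampen, b.sampen, rtol=1e-9)

    def test_signal_shorter_than_window_rejected(self):
        with pytest.raises(DomainError):
            sampen_profile(np.zeros(100), fs=1000.0)


class TestThresholdAndSegments:
    def make_profile(self, sampen, s=None, step=64, window=128):
        sampen = np.asarray(sampen, dtype=float)
        return ActivityProfile(
            sampen=sampen,
            window_starts=np.arange(len(sampen)) * step,
            fs=1000.0,
            window_len=window,
            r=0.1,
            params=SampEnParams(),
            s=None if s is None else np.asarray(s),
        )

    def test_threshold_is_inclusive_at_d(self):
        profile = threshold_activity(self.make_profile([0.2, 0.6, 0.9]), d=0.6)
        assert profile.s.tolist() == [0, 1, 1]

    def test_zero_threshold_marks_everything_active(self):
        profile = threshold_activity(self.make_profile([0.0, 0.3, 5.0]), d=0.0)
        assert profile.s.tolist() == [1, 1, 1]

    def test_threshold_above_cap_marks_nothing(self):
        cap = sampen_cap(128, 2)
        profile = threshold_activity(
            self.make_profile([0.5, cap, 1.0]), d=cap + 1.0
        )
        assert profile.s.tolist() == [0, 0, 0]

    def test_single_run_maps_to_sample_interval(self):
        profile = self.make_profile([0, 0, 0, 0], s=[0, 1, 1, 0])
        segments = extract_segments(profile, min_duration_s=0.0, merge_gap_s=0.0)
        assert len(segments) == 1
        assert (segments[0].start, segments[0].end) == (64, 2 * 64 + 128)

    def test_short_gap_is_merged(self):
        profile = self.make_profile([0, 0, 0], s=[1, 0, 1])
        merged = extract_segments(profile, min_duration_s=0.0, merge_gap_s=0.2)
        assert len(merged) == 1
        kept = extract_segments(profile, min_duration_s=0.0, merge_gap_s=0.0)
        assert len(kept) == 2

    def test_short_segments_dropped(self):
        # one-window run (128 ms) dropped; four-window run (320 ms) kept
        profile = self.make_profile([0] * 7, s=[1, 0, 0, 1, 1, 1, 1])
        segments = extract_segments(profile, min_duration_s=0.3, merge_gap_s=0.0)
        assert len(segments) == 1
        assert segments[0].duration_s >= 0.3

    def test_unthresholded_profile_rejected(self):
        with pytest.raises(DomainError):
            extract_segments(self.make_profile([0.1, 0.2]))


class TestBurstRecovery:
    def test_detected_segments_match_true_bursts(self, synth_config):
        """One segment per trial, well-overlapping the scheduled burst."""
        for seed in range(5):
            trial = generate_trial(synth_config, "shoulder_flexion", 50 + seed)
            proc = preprocess_pipeline(trial.recording)
            segments, _ = segment_recording(proc)
            assert len(segments) == 1
            iou = interval_iou(
                (segments[0].start, segments[0].end), trial.true_burst
            )
            assert iou >= 0.7
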