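"""Filtering, segmentation, normalization and window fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydrosip import (
    AccelStream,
    PeakSegment,
    PipelineConfig,
    SimConfig,
    detect_peak_segments,
    fit_window,
    moving_average,
    normalize_peak,
    preprocess_stream,
    simulate_session,
)


def brute_force_moving_average(values, window):
    """Independent oracle: centered mean with symmetric edge shrink."""
    n = len(values)
    half = (window - 1) // 2
    out = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = np.mean(values[i - h : i + h + 1])
    return out


class TestMovingAverage:
    def test_constant_stream_unchanged(self):
        out = moving_average(AccelStream(np.full(50, 3.7)), 5)
        np.testing.assert_allclose(out.values, 3.7)

    def test_ramp_window5_matches_windowed_mean(self):
        out = moving_average(AccelStream(np.arange(1.0, 8.0)), 5)
        # full centered window applies from index 2: mean(1..5) = 3, mean(2..6) = 4
        assert out.values[2] == pytest.approx(3.0)
        assert out.values[3] == pytest.approx(4.0)
        np.testing.assert_allclose(
            out.values, brute_force_moving_average(np.arange(1.0, 8.0), 5)
        )

    def test_impulse_response_support(self):
        v = np.zeros(21)
        v[10] = 1.0
        out = moving_average(AccelStream(v), 5).values
        assert np.count_nonzero(out) == 5
        np.testing.assert_allclose(out[8:13], 0.2)

    @pytest.mark.parametrize("window", [0, -3, 4])
    def test_invalid_window_rejected(self, window):
        with pytest.raises(ValueError):
            moving_average(AccelStream(np.ones(10)), window)

    @settings(deadline=None, max_examples=50)
    @given(
        values=st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=60),
        window=st.sampled_from([1, 3, 5, 7]),
    )
    def test_matches_brute_force_oracle(self, values, window):
        arr = np.asarray(values)
        out = moving_average(AccelStream(arr), window).values
        np.testing.assert_allclose(out, brute_force_moving_average(arr, window))


def bump(n, amplitude):
    t = np.linspace(0, 1, n)
    return amplitude * 0.5 * (1 - np.cos(2 * np.pi * t))


class TestDetectPeakSegments:
    def test_monotone_stream_yields_nothing(self):
        assert detect_peak_segments(AccelStream(np.linspace(0, 5, 40)), 0.2) == []

    def test_two_bumps_two_segments_with_heights(self):
        v = np.concatenate([
            np.zeros(5), bump(21, 1.0), np.zeros(5), bump(21, 2.0), np.zeros(5),
        ])
        # perturb the flat stretches so each has a genuine interior minimum
        for i in (2, 28, 54):
            v[i] -= 0.01
        segs = detect_peak_segments(AccelStream(v), 0.2)
        assert len(segs) == 2
        assert segs[0].raw_max == pytest.approx(1.0)
        assert segs[1].raw_max == pytest.approx(2.0)
        assert segs[0].start_index < segs[1].start_index

    def test_unterminated_bump_not_emitted(self):
        v = np.concatenate([np.zeros(5), bump(21, 1.0)[:12]])  # rises, stream ends
        v[2] -= 0.01
        assert detect_peak_segments(AccelStream(v), 0.2) == []

    def test_boundary_minima_below_threshold_and_interior_max(self):
        cfg = SimConfig(n_cycles=2, sips_per_cycle=4, noise_sd=0.02, seed=7)
        stream, _ = simulate_session(cfg)
        filt = moving_average(stream, 5)
        th = 1.3
        for seg in detect_peak_segments(filt, th):
            assert seg.raw_values[0] < th and seg.raw_values[-1] < th
            assert seg.raw_max > th
            assert len(seg.raw_values) >= 3


class TestNormalizePeak:
    def test_direct_evaluation(self):
        seg = PeakSegment(raw_values=[2.0, 4.0, 6.0], start_index=0)
        np.testing.assert_allclose(normalize_peak(seg), [10.0, 15.0, 20.0])

    def test_constant_segment_maps_to_floor(self):
        seg = PeakSegment(raw_values=[5.0, 5.0, 5.0], start_index=0)
        np.testing.assert_allclose(normalize_peak(seg), [10.0, 10.0, 10.0])

    @settings(deadline=None, max_examples=100)
    @given(
        values=st.lists(st.floats(-100, 100), min_size=3, max_size=40),
        scale=st.floats(0.01, 50),
        shift=st.floats(-100, 100),
    )
    def test_range_and_affine_invariance(self, values, scale, shift):
        arr = np.asarray(values)
        if np.ptp(arr) < 1e-6:
            return
        base = normalize_peak(PeakSegment(raw_values=arr, start_index=0))
        assert base.min() == pytest.approx(10.0)
        assert base.max() == pytest.approx(20.0)
        moved = normalize_peak(PeakSegment(raw_values=scale * arr + shift, start_index=0))
        np.testing.assert_allclose(moved, base, atol=1e-6)


class TestFitWindow:
    def test_short_input_right_padded(self):
        ep = fit_window(np.linspace(10, 20, 80))
        assert len(ep.norm_values) == 120
        assert ep.original_len == 80
        np.testing.assert_allclose(ep.norm_values[80:], 10.0)

    def test_exact_length_unchanged(self):
        v = np.linspace(10, 20, 120)
        ep = fit_window(v)
        np.testing.assert_allclose(ep.norm_values, v)
        assert ep.original_len == 120

    def test_long_input_truncated(self):
        v = np.linspace(10, 20, 150)
        ep = fit_window(v)
        np.testing.assert_allclose(ep.norm_values, v[:120])
        assert ep.original_len == 120

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fit_window([])


class TestPreprocessStream:
    def test_flat_stream_yields_no_episodes(self):
        assert preprocess_stream(AccelStream(np.ones(200))) == []

    def test_recovers_simulated_gestures(self):
        cfg = SimConfig(n_cycles=3, sips_per_cycle=4, noise_sd=0.0,
                        n_nonsip_events=0, seed=11)
        stream, truth = simulate_session(cfg)
        episodes = preprocess_stream(stream)
        assert len(episodes) == truth.n_sips
        # episodes arrive in temporal order with raw_max preserved
        starts = [e.start_index for e in episodes]
        assert starts == sorted(starts)

    def test_episode_invariants(self, default_config):
        cfg = SimConfig(n_cycles=2, sips_per_cycle=5, seed=5)
        stream, _ = simulate_session(cfg)
        for ep in preprocess_stream(stream, default_config):
            assert len(ep.norm_values) == default_config.episode_len
            assert ep.norm_values.min() >= default_config.norm_low - 1e-9
            assert ep.norm_values.max() <= default_config.norm_high + 1e-9
            np.testing.assert_allclose(
                ep.norm_values[ep.original_len:], default_config.pad_value
            )
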