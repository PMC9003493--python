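"""Raw-stream preprocessing: filter, segment, normalize, window-fit.

The chain turns a single-axis (bottle-vertical) accelerometer stream into
fixed-length *episodes*, the unit of sip/non-sip classification:

1. a centered 5-sample moving average removes sensor noise;
2. candidate gesture peaks are delimited by pairs of consecutive local
   minima that lie below a raw-domain segmentation threshold, provided at
   least one strict local maximum lies between them;
3. each extracted segment is affinely rescaled to [10, 20]
   (``norm = ((x - min) / (max - min) + 1) * 10``);
4. the normalized segment is fitted to a 120-sample window, right-padded
   with 10 (the range minimum) or truncated.

Local extrema use strict comparison; plateaus collapse to their first
sample, which makes segmentation deterministic on flat stretches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .config import PipelineConfig

logger = logging.getLogger(__name__)


@dataclass
class AccelStream:
    """Uniformly sampled single-axis accelerometer values."""

    values: np.ndarray
    sample_rate_hz: float = 20.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("AccelStream values must be one-dimensional")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.sample_rate_hz


@dataclass
class PeakSegment:
    """Points between two bounding sub-threshold local minima (inclusive)."""

    raw_values: np.ndarray
    start_index: int
    raw_max: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        self.raw_values = np.asarray(self.raw_values, dtype=float)
        if len(self.raw_values) < 3:
            raise ValueError("PeakSegment needs >= 3 samples (minima pair plus interior)")
        if np.isnan(self.raw_max):
            self.raw_max = float(self.raw_values.max())
        elif self.raw_max != self.raw_values.max():
            raise ValueError("raw_max must equal max(raw_values)")


@dataclass
class Episode:
    """Fixed-length normalized window; the classification unit.

    ``raw_max`` is the segment maximum in raw accelerometer units — the
    sip-height proxy p(i) carried through to the first-sip detector.
    """

    norm_values: np.ndarray
    raw_max: float
    original_len: int
    start_index: int = 0

    def __post_init__(self) -> None:
        self.norm_values = np.asarray(self.norm_values, dtype=float)


def moving_average(stream: AccelStream, window: int) -> AccelStream:
    """Centered moving-average filter; window shrinks symmetrically at edges.

    Output length equals input length. ``window`` must be odd so the
    centered window is unambiguous; at index ``i`` the effective half-width
    is ``min((window - 1) // 2, i, n - 1 - i)``.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window % 2 == 0:
        raise ValueError("window must be odd (centered filter)")
    v = stream.values
    n = len(v)
    if n == 0:
        raise ValueError("stream is empty")
    if window == 1:
        return AccelStream(v.copy(), stream.sample_rate_hz)
    half = (window - 1) // 2
    out = np.empty(n)
    # direct per-window sums (no running-sum cancellation); edges shrink
    if n >= window:
        out[half : n - half] = np.convolve(v, np.full(window, 1.0 / window), mode="valid")
    for i in range(n):
        h = min(half, i, n - 1 - i)
        if h < half:
            out[i] = v[i - h : i + h + 1].mean()
    return AccelStream(out, stream.sample_rate_hz)


def _plateau_extrema(values: np.ndarray) -> Tuple[List[int], List[int]]:
    """Strict local minima and maxima; plateaus collapse to their first index."""
    n = len(values)
    minima: List[int] = []
    maxima: List[int] = []
    if n < 3:
        return minima, maxima
    # run-length encode
    starts = [0]
    for i in range(1, n):
        if values[i] != values[i - 1]:
            starts.append(i)
    for r in range(1, len(starts) - 1):
        i = starts[r]
        prev_v = values[starts[r - 1]]
        next_v = values[starts[r + 1]]
        if values[i] < prev_v and values[i] < next_v:
            minima.append(i)
        elif values[i] > prev_v and values[i] > next_v:
            maxima.append(i)
    return minima, maxima


def default_segmentation_threshold(values: np.ndarray) -> float:
    """Adaptive raw-domain threshold: median + 0.25 * (max - median), noise-floored.

    The median estimates the resting (upright-bottle) baseline. The floor —
    eight median absolute deviations above the baseline — keeps a stream
    that contains nothing but sensor noise from being segmented at all.
    """
    baseline = float(np.median(values))
    mad = float(np.median(np.abs(values - baseline)))
    return baseline + max(0.25 * (float(values.max()) - baseline), 8.0 * mad)


def detect_peak_segments(
    stream: AccelStream, segmentation_threshold: Optional[float] = None
) -> List[PeakSegment]:
    """Extract candidate gesture peaks from a filtered stream.

    A segment spans two consecutive local minima whose values fall below
    ``segmentation_threshold`` and must contain at least one strict local
    maximum between them that rises above the threshold (so sub-threshold
    noise ripple between two quiet minima is not a gesture). Segments share
    boundary minima but never overlap otherwise; a gesture that never
    returns below the threshold before the stream ends is not emitted.
    """
    v = stream.values
    if len(v) == 0:
        return []
    if segmentation_threshold is None:
        segmentation_threshold = default_segmentation_threshold(v)
    minima, maxima = _plateau_extrema(v)
    low_minima = [i for i in minima if v[i] < segmentation_threshold]
    maxima_arr = np.asarray(maxima, dtype=int)
    segments: List[PeakSegment] = []
    for left, right in zip(low_minima, low_minima[1:]):
        if maxima_arr.size:
            interior = maxima_arr[(maxima_arr > left) & (maxima_arr < right)]
        else:
            interior = maxima_arr
        if interior.size == 0 or v[interior].max() <= segmentation_threshold:
            continue
        # a strict interior maximum always exceeds both strict-minimum
        # delimiters; asserted here as a structural invariant
        assert v[interior].max() > max(v[left], v[right])
        segments.append(PeakSegment(raw_values=v[left : right + 1], start_index=left))
    logger.info("detect_peak_segments: %d samples in, %d segments", len(v), len(segments))
    return segments


def normalize_peak(
    segment: PeakSegment, config: Optional[PipelineConfig] = None
) -> np.ndarray:
    """Affinely rescale a raw segment to [norm_low, norm_high].

    With the default range [10, 20] this is
    ``((x - min(x)) / (max(x) - min(x)) + 1) * 10``. A constant (degenerate)
    segment maps to all ``norm_low``.
    """
    config = config or PipelineConfig()
    x = segment.raw_values
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return np.full(len(x), config.norm_low)
    span = config.norm_high - config.norm_low
    return config.norm_low + (x - lo) / (hi - lo) * span


def fit_window(
    norm_values: Sequence[float],
    config: Optional[PipelineConfig] = None,
    raw_max: float = float("nan"),
    start_index: int = 0,
) -> Episode:
    """Fit a normalized segment into a fixed ``episode_len`` window.

    Short inputs are right-padded with ``pad_value``; long inputs keep
    their first ``episode_len`` samples. ``original_len`` records the
    pre-padding length, capped at ``episode_len``.
    """
    config = config or PipelineConfig()
    arr = np.asarray(norm_values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot fit an empty segment")
    n = config.episode_len
    original = min(len(arr), n)
    if len(arr) >= n:
        out = arr[:n].copy()
    else:
        out = np.full(n, config.pad_value)
        out[: len(arr)] = arr
    return Episode(norm_values=out, raw_max=raw_max, original_len=original,
                   start_index=start_index)


def preprocess_stream(
    stream: AccelStream, config: Optional[PipelineConfig] = None
) -> List[Episode]:
    """Full chain: moving average -> segmentation -> normalization -> window fit."""
    config = config or PipelineConfig()
    if len(stream) == 0:
        raise ValueError("stream is empty")
    filtered = moving_average(stream, config.ma_window)
    segments = detect_peak_segments(filtered, config.segmentation_threshold)
    episodes = [
        fit_window(normalize_peak(seg, config), config,
                   raw_max=seg.raw_max, start_index=seg.start_index)
        for seg in segments
    ]
    logger.info(
        "preprocess_stream: %d samples -> %d segments -> %d episodes",
        len(stream), len(segments), len(episodes),
    )
    return episodes
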