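"""Synthetic drinking-session generator.

Emulates the statistical structure the detection pipeline relies on, so
every stage can be exercised without recorded sensor data:

* the baseline is the upright-bottle gravity reading on the vertical axis
  (1.0 in arbitrary raw units; only relative amplitudes matter after
  normalization);
* a sip is a smooth raised-cosine tilt bump of 1-6 s whose amplitude grows
  sip over sip within a drinking cycle (an emptier bottle must be tilted
  further) and resets at a refill — the first sip of each cycle carries the
  cycle's minimum amplitude;
* non-sip activity kernels are oscillatory (walking ~2 Hz, stairs slower
  and larger, bottle-in-bag damped), noisy (stationary, moving car) or
  spiky (sub-second in-hand fidgeting);
* additive Gaussian sensor noise, fully seeded.

Per-sip true volumes within a cycle are equal (bottle volume / sips in the
cycle) by default, matching the estimator's constant-VSip model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .config import PipelineConfig
from .preprocessing import AccelStream, preprocess_stream

ACTIVITY_CLASSES = ("walk_flat", "walk_stairs", "bag_walk", "stationary", "car", "fidget")


@dataclass
class SimConfig:
    """Generative parameters of a synthetic drinking session."""

    sample_rate_hz: float = 20.0
    n_cycles: int = 2
    sips_per_cycle: Union[int, Tuple[int, int]] = 5
    sip_duration_s: Tuple[float, float] = (1.5, 4.0)
    baseline: float = 1.0
    sip_base_amplitude: float = 1.0
    within_cycle_amplitude_increment: float = 0.15
    refill_amplitude_drop: Optional[float] = None  # None -> reset to base amplitude
    gap_s: Tuple[float, float] = (2.0, 5.0)
    n_nonsip_events: int = 4
    nonsip_mix: Optional[Dict[str, float]] = None  # uniform over classes when None
    noise_sd: float = 0.02
    bottle_volume_ml: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.sip_duration_s
        if not (1.0 <= lo <= hi <= 6.0):
            raise ValueError("sip durations must lie within [1, 6] s")
        if self.within_cycle_amplitude_increment <= 0:
            raise ValueError("within-cycle amplitude increment must be positive")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")


@dataclass
class SipInterval:
    start: int
    end: int
    amplitude: float
    is_first_sip: bool
    true_volume_ml: float


@dataclass
class GroundTruth:
    """Labels the generator attaches to a synthetic session."""

    sips: List[SipInterval] = field(default_factory=list)
    nonsip_intervals: List[Tuple[int, int, str]] = field(default_factory=list)
    refill_indices: List[int] = field(default_factory=list)
    v_bottle: float = 500.0

    @property
    def n_sips(self) -> int:
        return len(self.sips)

    def true_cumulative(self) -> np.ndarray:
        return np.cumsum([s.true_volume_ml for s in self.sips])


def _raised_cosine(n: int, amplitude: float) -> np.ndarray:
    t = np.arange(n) / max(n - 1, 1)
    return amplitude * 0.5 * (1.0 - np.cos(2.0 * np.pi * t))


def _quiet(n: int, fs: float, dip: float = 0.05) -> np.ndarray:
    """A resting stretch: flat, with a small settle dip at its center.

    The dip models the bottle being set down / re-gripped; it guarantees a
    sub-baseline local minimum inside every quiet stretch, so gestures are
    delimited even in noise-free streams where a perfectly flat gap would
    collapse into a single plateau.
    """
    out = np.zeros(n)
    width = max(int(0.2 * fs), 3)
    if n > width + 2:
        start = (n - width) // 2
        out[start : start + width] = -_raised_cosine(width, dip)
    return out


def _nonsip_kernel(kind: str, fs: float, rng: np.random.Generator) -> np.ndarray:
    """A zero-baseline activity snippet; added on top of the session baseline."""
    if kind == "walk_flat":
        dur = rng.uniform(3.0, 6.0)
        t = np.arange(int(dur * fs)) / fs
        return 0.35 * np.abs(np.sin(2.0 * np.pi * 2.0 * t)) + rng.normal(0, 0.03, t.size)
    if kind == "walk_stairs":
        dur = rng.uniform(3.0, 6.0)
        t = np.arange(int(dur * fs)) / fs
        return 0.5 * np.abs(np.sin(2.0 * np.pi * 1.5 * t)) + rng.normal(0, 0.05, t.size)
    if kind == "bag_walk":
        dur = rng.uniform(3.0, 6.0)
        t = np.arange(int(dur * fs)) / fs
        return 0.25 * np.abs(np.sin(2.0 * np.pi * 2.0 * t)) + rng.normal(0, 0.04, t.size)
    if kind == "stationary":
        n = int(rng.uniform(2.0, 5.0) * fs)
        return rng.normal(0, 0.02, n)
    if kind == "car":
        dur = rng.uniform(2.0, 5.0)
        t = np.arange(int(dur * fs)) / fs
        return 0.08 * np.sin(2.0 * np.pi * 0.7 * t) + rng.normal(0, 0.05, t.size)
    if kind == "fidget":
        # a few sub-second spikes
        n = int(rng.uniform(1.5, 3.0) * fs)
        out = np.zeros(n)
        for _ in range(rng.integers(2, 5)):
            width = int(rng.uniform(0.15, 0.6) * fs)
            start = rng.integers(0, max(n - width, 1))
            out[start : start + width] += _raised_cosine(width, rng.uniform(0.5, 1.4))
        return out
    raise ValueError(f"unknown activity class {kind!r}")


def _cycle_sizes(cfg: SimConfig, rng: np.random.Generator) -> List[int]:
    if isinstance(cfg.sips_per_cycle, int):
        return [cfg.sips_per_cycle] * cfg.n_cycles
    lo, hi = cfg.sips_per_cycle
    return [int(rng.integers(lo, hi + 1)) for _ in range(cfg.n_cycles)]


def simulate_session(config: SimConfig) -> Tuple[AccelStream, GroundTruth]:
    """Generate a labeled accelerometer stream for one drinking session."""
    rng = np.random.default_rng(config.seed)
    fs = config.sample_rate_hz
    sizes = _cycle_sizes(config, rng)
    mix_classes, mix_weights = _normalized_mix(config.nonsip_mix)

    # schedule: for each cycle, its sips in order; non-sip events are
    # spliced into randomly chosen gaps
    chunks: List[np.ndarray] = []
    truth = GroundTruth(v_bottle=config.bottle_volume_ml)
    cursor = 0

    def push(chunk: np.ndarray) -> Tuple[int, int]:
        nonlocal cursor
        chunks.append(chunk)
        start = cursor
        cursor += len(chunk)
        return start, cursor - 1

    def push_gap() -> None:
        n = int(rng.uniform(*config.gap_s) * fs)
        push(_quiet(n, fs))

    nonsip_slots = (
        sorted(rng.choice(sum(sizes) + config.n_cycles,
                          size=config.n_nonsip_events, replace=True).tolist())
        if config.n_nonsip_events else []
    )
    event_counter = 0
    base_amp = config.sip_base_amplitude
    push_gap()
    for cycle, n_sips in enumerate(sizes):
        if config.refill_amplitude_drop is not None and cycle > 0:
            prev_last = base_amp + (sizes[cycle - 1] - 1) * config.within_cycle_amplitude_increment
            base_amp = prev_last - config.refill_amplitude_drop
        else:
            base_amp = config.sip_base_amplitude
        truth.refill_indices.append(cursor)
        for rank in range(n_sips):
            while nonsip_slots and nonsip_slots[0] <= event_counter:
                nonsip_slots.pop(0)
                kind = str(rng.choice(mix_classes, p=mix_weights))
                s, e = push(_nonsip_kernel(kind, fs, rng))
                truth.nonsip_intervals.append((s, e, kind))
                push_gap()
            amp = base_amp + rank * config.within_cycle_amplitude_increment
            dur = rng.uniform(*config.sip_duration_s)
            s, e = push(_raised_cosine(int(dur * fs), amp))
            truth.sips.append(SipInterval(
                start=s, end=e, amplitude=amp, is_first_sip=(rank == 0),
                true_volume_ml=config.bottle_volume_ml / n_sips,
            ))
            push_gap()
            event_counter += 1
    while nonsip_slots:
        nonsip_slots.pop(0)
        kind = str(rng.choice(mix_classes, p=mix_weights))
        s, e = push(_nonsip_kernel(kind, fs, rng))
        truth.nonsip_intervals.append((s, e, kind))
        push_gap()
    values = config.baseline + np.concatenate(chunks)
    if config.noise_sd > 0:
        values = values + rng.normal(0, config.noise_sd, values.size)
    return AccelStream(values, fs), truth


def _normalized_mix(mix: Optional[Dict[str, float]]):
    if mix is None:
        mix = {k: 1.0 for k in ACTIVITY_CLASSES}
    classes = [k for k, w in mix.items() if w > 0]
    for k in classes:
        if k not in ACTIVITY_CLASSES:
            raise ValueError(f"unknown activity class {k!r}")
    weights = np.array([mix[k] for k in classes], dtype=float)
    return classes, weights / weights.sum()


def simulate_episode_dataset(
    n_sips: int,
    n_nonsips: int,
    config: Optional[SimConfig] = None,
    pipeline_config: Optional[PipelineConfig] = None,
    seed: Optional[int] = None,
):
    """Balanced (or user-set) labeled episodes via the real preprocessing path.

    Each sip instance is a lone raised-cosine bump in a quiet stream; each
    non-sip instance is one activity kernel. Both pass through the actual
    filter/segment/normalize/window chain, and the resulting episodes carry
    labels (1 = sip, 0 = non-sip).

    Returns ``(episodes, labels)``.
    """
    cfg = config or SimConfig()
    pcfg = pipeline_config or PipelineConfig(sample_rate_hz=cfg.sample_rate_hz)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    fs = cfg.sample_rate_hz
    mix_classes, mix_weights = _normalized_mix(cfg.nonsip_mix)
    pad = _quiet(int(2.0 * fs), fs)

    episodes, labels = [], []
    for _ in range(n_sips):
        amp = rng.uniform(cfg.sip_base_amplitude,
                          cfg.sip_base_amplitude + 4 * cfg.within_cycle_amplitude_increment)
        dur = rng.uniform(*cfg.sip_duration_s)
        chunk = np.concatenate([pad, _raised_cosine(int(dur * fs), amp), pad])
        values = cfg.baseline + chunk + rng.normal(0, cfg.noise_sd, chunk.size)
        eps = preprocess_stream(AccelStream(values, fs), pcfg)
        if eps:
            best = max(eps, key=lambda e: e.raw_max)
            episodes.append(best)
            labels.append(1)
    attempts = 0
    while sum(1 for l in labels if l == 0) < n_nonsips:
        attempts += 1
        if attempts > 50 * max(n_nonsips, 1):
            raise RuntimeError(
                "non-sip kernels are not producing episodes; the requested "
                "activity mix may be entirely sub-threshold (e.g. stationary only)"
            )
        kind = str(rng.choice(mix_classes, p=mix_weights))
        chunk = np.concatenate([pad, _nonsip_kernel(kind, fs, rng), pad])
        values = cfg.baseline + chunk + rng.normal(0, cfg.noise_sd, chunk.size)
        eps = preprocess_stream(AccelStream(values, fs), pcfg)
        need = n_nonsips - sum(1 for l in labels if l == 0)
        for e in eps[:need]:
            episodes.append(e)
            labels.append(0)
    return episodes, np.asarray(labels, dtype=int)


def simulate_sip_height_sequence(
    n_cycles: int,
    sips_per_cycle: Union[int, Sequence[int]],
    base: float = 2.0,
    increment: float = 0.15,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Sip-height series with within-cycle growth and refill resets.

    Bypasses the signal layer for fast first-sip-detector tests. Returns
    ``(heights, labels)`` with labels marking each cycle's first sip.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    sizes = ([sips_per_cycle] * n_cycles if isinstance(sips_per_cycle, int)
             else list(sips_per_cycle))
    if any(s < 1 for s in sizes):
        raise ValueError("sips_per_cycle must be >= 1")
    rng = np.random.default_rng(seed)
    heights, labels = [], []
    for n in sizes:
        for rank in range(n):
            h = base + rank * increment
            if noise_sd > 0:
                h += rng.normal(0, noise_sd)
            heights.append(h)
            labels.append(1 if rank == 0 else 0)
    return np.asarray(heights), np.asarray(labels, dtype=int)
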