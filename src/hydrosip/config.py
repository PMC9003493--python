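"""Pipeline configuration.

A single dataclass holds every constant the processing chain depends on:
the 20 Hz effective sampling rate, the 5-sample moving-average window, the
120-sample episode window (6 s of gesture at 20 Hz), the [10, 20]
normalization range with pad value 10, and the two distinct thresholds that
the literature overloads under one symbol — a raw-domain segmentation
threshold used when pairing sub-threshold local minima, and the
normalized-domain threshold (10) used when counting peak samples in the
feature extractor.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import yaml


@dataclass
class PipelineConfig:
    """All tunable constants of the sip-detection / volume-estimation chain.

    Parameters
    ----------
    sample_rate_hz:
        Effective accelerometer sampling rate in Hz. Every duration-like
        constant downstream (120 samples = 6 s) assumes 20 Hz.
    ma_window:
        Moving-average filter length in samples (odd).
    episode_len:
        Fixed episode window length in samples.
    pad_value:
        Value used to right-pad short episodes; equals the minimum of the
        normalization range.
    norm_low, norm_high:
        Target range of the peak normalization.
    th_norm:
        Normalized-domain threshold above which a sample counts toward the
        peak-count and peak-duration features.
    segmentation_threshold:
        Raw-domain threshold below which a local minimum qualifies as a
        segment boundary. ``None`` selects an adaptive per-stream estimate:
        median + 0.25 * (max - median).
    stable_fraction:
        Width of the "stable portion" band near the episode maximum, as a
        fraction (0.20 = within 20% of the highest point).
    stable_mode:
        ``"multiplicative"`` counts samples >= (1 - stable_fraction) * max;
        ``"additive"`` counts samples >= max - stable_fraction *
        (norm_high - norm_low).
    decision_threshold:
        Probability cutoff of both binary classifiers.
    bottle_volume_ml:
        Known bottle volume for the volume estimator.
    rng_seed:
        Seed for every randomized operation configured through this object.
    """

    sample_rate_hz: float = 20.0
    ma_window: int = 5
    episode_len: int = 120
    pad_value: float = 10.0
    norm_low: float = 10.0
    norm_high: float = 20.0
    th_norm: float = 10.0
    segmentation_threshold: Optional[float] = None
    stable_fraction: float = 0.20
    stable_mode: str = "multiplicative"
    decision_threshold: float = 0.5
    bottle_volume_ml: float = 500.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.ma_window < 1:
            raise ValueError("ma_window must be >= 1")
        if self.episode_len <= 0:
            raise ValueError("episode_len must be positive")
        if not self.norm_low < self.norm_high:
            raise ValueError("norm_low must be < norm_high")
        if not 0 < self.stable_fraction < 1:
            raise ValueError("stable_fraction must be in (0, 1)")
        if self.stable_mode not in ("multiplicative", "additive"):
            raise ValueError("stable_mode must be 'multiplicative' or 'additive'")
        if not 0 < self.decision_threshold < 1:
            raise ValueError("decision_threshold must be in (0, 1)")
        if self.bottle_volume_ml <= 0:
            raise ValueError("bottle_volume_ml must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
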