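"""First-sip detection from sip-height gradients.

As a bottle empties, the drinker must tilt it further to reach the liquid,
so the raw-domain sip height p(i) (maximum inclination proxy of the i-th
detected sip) rises sip over sip within a drinking cycle — and drops
sharply at the first sip after a refill. Three lagged differences capture
that signature:

    F1(i) = p(i) - p(i-1)
    F2(i) = p(i) - p(i-2)
    F3(i) = p(i) - p(i-3)

All three are strongly negative exactly at a first sip. A tiny dense
network (3 inputs, one small hidden layer) maps the feature triple to a
first-sip probability. Early indices (i <= 3) clamp the missing lag
references to p(1), giving near-zero neutral features at session start;
the very first sip of a session is labeled a first-sip by convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .nn import DenseNetModel, NetArchitecture, TrainConfig, train


@dataclass
class SipEvent:
    """A detected sip: 1-based counter, raw-domain height, optional time."""

    index: int
    height: float
    time: Optional[float] = None


@dataclass
class FirstSipFeatures:
    f1: float
    f2: float
    f3: float

    def to_array(self) -> np.ndarray:
        return np.array([self.f1, self.f2, self.f3], dtype=float)


def compute_gradient_features(heights: Sequence[float], i: int) -> FirstSipFeatures:
    """Lagged height differences at 1-based sip index ``i``.

    Lag references before the first sip clamp to ``heights[0]``.
    """
    h = np.asarray(heights, dtype=float)
    if h.size == 0:
        raise ValueError("empty height sequence")
    if not 1 <= i <= h.size:
        raise ValueError(f"sip index {i} outside 1..{h.size}")
    p_i = h[i - 1]
    lags = [h[max(i - 1 - j, 0)] for j in (1, 2, 3)]
    return FirstSipFeatures(*(float(p_i - ref) for ref in lags))


def gradient_feature_matrix(heights: Sequence[float]) -> np.ndarray:
    """(n_sips, 3) matrix of lagged-difference features for a height series."""
    return np.vstack(
        [compute_gradient_features(heights, i).to_array()
         for i in range(1, len(heights) + 1)]
    ) if len(heights) else np.empty((0, 3))


def detect_first_sip(model: DenseNetModel, features: FirstSipFeatures) -> bool:
    return bool(model.classify(features.to_array()))


def default_firstsip_train_config(seed: int = 0) -> TrainConfig:
    """Adam, 150 epochs, batch 10, 80:20 split — the detector's recipe."""
    return TrainConfig(optimizer="adam", epochs=150, batch_size=10, seed=seed)


def train_first_sip_detector(
    heights: Sequence[float],
    is_first_sip: Sequence[int],
    hidden_size: int = 3,
    config: Optional[TrainConfig] = None,
    seed: int = 0,
) -> Tuple[DenseNetModel, dict]:
    """Train the first-sip detector on a labeled sip-height sequence.

    Cycles contain a single first-sip among many sips, so classes are
    weighted by inverse frequency to keep the minority class from being
    ignored.
    """
    config = config or default_firstsip_train_config(seed)
    y = np.asarray(is_first_sip, dtype=int)
    X = gradient_feature_matrix(heights)
    counts = np.bincount(y, minlength=2)
    if counts.min() == 0:
        raise ValueError("both first-sip and non-first-sip examples are required")
    class_w = len(y) / (2.0 * counts)
    sample_weight = class_w[y]
    arch = NetArchitecture(n_inputs=3, hidden_sizes=(hidden_size,), n_outputs=1)
    return train(X, y, arch, config, sample_weight=sample_weight)


def label_sequence(
    model: DenseNetModel, heights: Sequence[float]
) -> List[bool]:
    """Run the detector across a full height sequence, in arrival order.

    The very first sip of a session opens the first drinking cycle and is
    flagged a first-sip by convention — its clamped features are the
    uninformative (0, 0, 0).
    """
    out = [
        detect_first_sip(model, compute_gradient_features(heights, i))
        for i in range(1, len(heights) + 1)
    ]
    if out:
        out[0] = True
    return out
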