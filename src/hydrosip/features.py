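"""Five-feature vector summarizing an episode for sip/non-sip classification.

* ``n_peaks`` — strict local maxima of the normalized window above the
  normalized threshold (10); sips tilt the bottle once, most non-sip
  gestures oscillate.
* ``max_peak_height`` — the segment maximum in RAW accelerometer units,
  i.e. the maximum tilt the bottle experienced. The normalized maximum is
  identically 20 for every non-constant segment, so the raw-domain value is
  the only informative reading.
* ``peak_duration`` — samples above the normalized threshold; drinking
  holds the tilt, so sips score high.
* ``n_stable`` — samples within the stability band near the window maximum
  (within 20% of the highest point by default); the "held at the mouth"
  plateau.
* ``last_height`` — normalized value of the final window sample; > 10 only
  when a gesture overruns the 6 s window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import PipelineConfig
from .preprocessing import Episode, _plateau_extrema

FEATURE_NAMES = ("n_peaks", "max_peak_height", "peak_duration", "n_stable", "last_height")


@dataclass
class SipFeatures:
    n_peaks: int
    max_peak_height: float
    peak_duration: int
    n_stable: int
    last_height: float

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.n_peaks, self.max_peak_height, self.peak_duration,
             self.n_stable, self.last_height],
            dtype=float,
        )


def extract_sip_features(
    episode: Episode, config: Optional[PipelineConfig] = None
) -> SipFeatures:
    config = config or PipelineConfig()
    v = episode.norm_values
    _, maxima = _plateau_extrema(v)
    n_peaks = int(sum(1 for i in maxima if v[i] > config.th_norm))
    peak_duration = int(np.sum(v > config.th_norm))
    top = float(v.max())
    if top <= config.th_norm:
        # no peak at all (e.g. an all-pad window): no stable portion either
        n_stable = 0
    else:
        if config.stable_mode == "multiplicative":
            band_floor = (1.0 - config.stable_fraction) * top
        else:
            band_floor = top - config.stable_fraction * (config.norm_high - config.norm_low)
        n_stable = int(np.sum(v >= band_floor))
    return SipFeatures(
        n_peaks=n_peaks,
        max_peak_height=float(episode.raw_max),
        peak_duration=peak_duration,
        n_stable=n_stable,
        last_height=float(v[-1]),
    )


def features_matrix(episodes, config: Optional[PipelineConfig] = None) -> np.ndarray:
    """Stack per-episode feature vectors into an (n_episodes, 5) array."""
    config = config or PipelineConfig()
    if not episodes:
        return np.empty((0, len(FEATURE_NAMES)))
    return np.vstack([extract_sip_features(e, config).to_array() for e in episodes])
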