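"""Self-correcting cumulative fluid-intake estimation.

Each detected sip adds the running per-sip volume estimate VSip to the
cumulative intake Vintake. Within a drinking cycle (the period between two
refills) the displayed cycle consumption is capped at the known bottle
volume: once the estimate reaches a full bottle it freezes until the next
first-sip detection. At each detected first sip the completed cycle is
snapped onto an integer number of bottle volumes:

    k* = argmin_{k >= 1} | cycle_uncapped - k * v_bottle |

where ``cycle_uncapped`` is what the cycle would have accumulated without
the cap (ties break toward the smaller k). The signed correction
Verr = k* * v_bottle - (capped cycle consumption) moves the running total
onto k* full bottles, and VSip is re-estimated as k* * v_bottle / Scount
with Scount the number of sips in the closed cycle. Missed sips therefore
bias the estimate only within a cycle; the error is erased (down to the
first-sip's own share) at every refill boundary, and an entire missed
refill is recovered with k* = 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import PipelineConfig
from .first_sip import SipEvent, label_sequence
from .metrics import classify_episodes
from .nn import DenseNetModel
from .preprocessing import AccelStream, preprocess_stream

logger = logging.getLogger(__name__)


@dataclass
class VolumeState:
    """Running state of the cumulative-intake estimator."""

    v_bottle: float
    v_sip: float
    v_intake: float = 0.0
    s_count: int = 0
    cycle_start_intake: float = 0.0
    cycle_uncapped: float = 0.0
    history: List[Tuple[int, float, bool]] = field(default_factory=list)

    @property
    def cycle_consumed(self) -> float:
        return self.v_intake - self.cycle_start_intake


def init_state(
    v_bottle: float, expected_sips_per_bottle: int,
    config: Optional[PipelineConfig] = None,
) -> VolumeState:
    """Cold-start state; VSip = v_bottle / expected sips, self-corrected later."""
    if v_bottle <= 0:
        raise ValueError("v_bottle must be positive")
    if expected_sips_per_bottle < 1:
        raise ValueError("expected_sips_per_bottle must be >= 1")
    return VolumeState(v_bottle=v_bottle, v_sip=v_bottle / expected_sips_per_bottle)


def _snap_multiple(uncapped: float, v_bottle: float) -> int:
    """Integer number of bottles nearest to the uncapped cycle consumption.

    k >= 1 always (a completed cycle implies at least one bottle); a
    residual of exactly half a bottle breaks toward the smaller k.
    """
    k = int(np.floor(uncapped / v_bottle))
    if uncapped - k * v_bottle > 0.5 * v_bottle:
        k += 1
    return max(1, k)


def update(
    state: VolumeState, sip: SipEvent, is_first_sip: bool,
    literal_order: bool = False,
) -> VolumeState:
    """Advance the estimator by one detected sip; returns a new state.

    ``literal_order=True`` applies the add-then-correct ordering at a first
    sip (the first sip's volume enters the cycle being closed) instead of
    the default close-then-open ordering, in which the snap covers exactly
    the sips that emptied the bottle.
    """
    s = replace(state, history=list(state.history))
    if is_first_sip and s.s_count == 0:
        # session start (or duplicate first-sip): no completed cycle to
        # correct — treat as the cycle-opening sip
        s.s_count = 1
        s.v_intake += min(s.v_sip, s.v_bottle - s.cycle_consumed)
        s.cycle_uncapped += s.v_sip
        s.history.append((sip.index, s.v_intake, True))
        return s
    if not is_first_sip:
        s.s_count += 1
        s.v_intake += min(s.v_sip, s.v_bottle - s.cycle_consumed)
        s.cycle_uncapped += s.v_sip
        s.history.append((sip.index, s.v_intake, False))
        return s
    if literal_order:
        # add-then-correct: the first sip joins the cycle being closed
        s.s_count += 1
        s.v_intake += min(s.v_sip, s.v_bottle - s.cycle_consumed)
        s.cycle_uncapped += s.v_sip
        k = _snap_multiple(s.cycle_uncapped, s.v_bottle)
        s.v_intake += k * s.v_bottle - s.cycle_consumed
        s.v_sip = k * s.v_bottle / s.s_count
        s.cycle_start_intake = s.v_intake
        s.cycle_uncapped = 0.0
        s.s_count = 0
        s.history.append((sip.index, s.v_intake, True))
        return s
    # first sip: close the previous cycle, snap it to k* full bottles
    k = _snap_multiple(s.cycle_uncapped, s.v_bottle)
    v_err = k * s.v_bottle - s.cycle_consumed
    s.v_intake += v_err
    if s.s_count >= 1:
        s.v_sip = k * s.v_bottle / s.s_count
    logger.info("first sip %d: k*=%d, Verr=%+.1f mL, VSip=%.1f mL",
                sip.index, k, v_err, s.v_sip)
    # open the new cycle with this first sip
    s.cycle_start_intake = s.v_intake
    s.cycle_uncapped = 0.0
    s.s_count = 1
    s.v_intake += min(s.v_sip, s.v_bottle)
    s.cycle_uncapped += s.v_sip
    s.history.append((sip.index, s.v_intake, True))
    return s


def estimate_from_sip_events(
    heights: Sequence[float],
    first_sip_flags: Sequence[bool],
    v_bottle: float,
    expected_sips_per_bottle: int = 10,
    times: Optional[Sequence[float]] = None,
    config: Optional[PipelineConfig] = None,
) -> Tuple[VolumeState, List[Dict]]:
    """Run the estimator over an already-detected sip sequence."""
    state = init_state(v_bottle, expected_sips_per_bottle, config)
    trajectory: List[Dict] = []
    for i, (h, flag) in enumerate(zip(heights, first_sip_flags), start=1):
        t = float(times[i - 1]) if times is not None else None
        state = update(state, SipEvent(index=i, height=float(h), time=t), bool(flag))
        trajectory.append({
            "sip_index": i,
            "time": t,
            "v_intake_ml": state.v_intake,
            "is_first_sip": bool(flag),
        })
    return state, trajectory


def run_session(
    source,
    sip_model: Optional[DenseNetModel] = None,
    firstsip_model: Optional[DenseNetModel] = None,
    config: Optional[PipelineConfig] = None,
    expected_sips_per_bottle: int = 10,
    true_trajectory: Optional[Sequence[float]] = None,
) -> Dict:
    """End-to-end intake estimation for one session.

    ``source`` is either an :class:`AccelStream` (the full pipeline runs:
    preprocess -> sip classification -> first-sip detection -> estimator)
    or a sequence of sip heights (detection layers already applied; the
    first-sip detector still runs, or every-cycle flags may be passed via
    a (heights, flags) tuple).

    When ``true_trajectory`` gives the true cumulative volume after each
    detected sip, a per-step percentage error is included.
    """
    config = config or PipelineConfig()
    flags: Optional[List[bool]] = None
    times: Optional[List[float]] = None
    if isinstance(source, AccelStream):
        if sip_model is None:
            raise ValueError("sip_model required for raw-stream input")
        episodes = preprocess_stream(source, config)
        preds = classify_episodes(sip_model, episodes, config)
        sip_eps = [e for e, p in zip(episodes, preds) if p["label"] == 1]
        heights = [e.raw_max for e in sip_eps]
        times = [e.start_index / source.sample_rate_hz for e in sip_eps]
    elif isinstance(source, tuple) and len(source) == 2:
        heights, flags = list(source[0]), [bool(f) for f in source[1]]
    else:
        heights = [float(h) for h in source]

    if flags is None:
        if firstsip_model is None:
            raise ValueError("firstsip_model required when first-sip flags not given")
        flags = label_sequence(firstsip_model, heights)

    state, trajectory = estimate_from_sip_events(
        heights, flags, config.bottle_volume_ml, expected_sips_per_bottle,
        times=times, config=config,
    )
    if true_trajectory is not None:
        for step, true_v in zip(trajectory, true_trajectory):
            step["true_v_ml"] = float(true_v)
            step["pct_error"] = (
                abs(step["v_intake_ml"] - true_v) / true_v * 100.0 if true_v else None
            )
    logger.info("run_session: %d sips, %d first-sips, intake %.1f mL",
                len(heights), sum(flags), state.v_intake)
    return {"state": state, "trajectory": trajectory,
            "heights": heights, "first_sip_flags": flags}
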