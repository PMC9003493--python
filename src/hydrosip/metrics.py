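"""Sip/non-sip classification over episodes and its evaluation metrics.

The evaluation follows the confusion-count form used for gesture
classifiers in this domain:

    tp = Nsd / Ns            (sips correctly detected / true sips)
    fp = (Nns - Nnsd) / Nns  (non-sips misread as sips / true non-sips)
    accuracy = (Nsd + Nnsd) / (Ns + Nns)

where Nsd and Nnsd are correctly detected sips and non-sips. Percentages
are reported floored to integers, so e.g. 26.82% prints as 26%.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from .config import PipelineConfig
from .features import features_matrix
from .nn import DenseNetModel
from .preprocessing import Episode

logger = logging.getLogger(__name__)


@dataclass
class ClassificationMetrics:
    n_sips: int
    n_nonsips: int
    n_sips_detected: int
    n_nonsips_detected: int

    @property
    def tp(self) -> Optional[float]:
        """True-positive rate over sips; None when no sips in truth."""
        return self.n_sips_detected / self.n_sips if self.n_sips else None

    @property
    def fp(self) -> Optional[float]:
        """Fraction of non-sips misclassified as sips; None when no non-sips."""
        if not self.n_nonsips:
            return None
        return (self.n_nonsips - self.n_nonsips_detected) / self.n_nonsips

    @property
    def accuracy(self) -> float:
        total = self.n_sips + self.n_nonsips
        return (self.n_sips_detected + self.n_nonsips_detected) / total

    @staticmethod
    def _pct(x: Optional[float]) -> Optional[int]:
        return None if x is None else math.floor(100.0 * x)

    def to_dict(self) -> Dict:
        return {
            "Ns": self.n_sips,
            "Nns": self.n_nonsips,
            "Nsd": self.n_sips_detected,
            "Nnsd": self.n_nonsips_detected,
            "tp_pct": self._pct(self.tp),
            "fp_pct": self._pct(self.fp),
            "accuracy_pct": self._pct(self.accuracy),
        }


def classify_episodes(
    model: DenseNetModel,
    episodes: Sequence[Episode],
    config: Optional[PipelineConfig] = None,
) -> List[Dict]:
    """Predict sip (1) / non-sip (0) per episode, order preserved."""
    config = config or PipelineConfig()
    if not episodes:
        return []
    X = features_matrix(episodes, config)
    probas = model.forward(X)
    out = [
        {"label": int(p >= model.decision_threshold), "proba": float(p)}
        for p in probas
    ]
    logger.info("classify_episodes: %d episodes, %d sips detected",
                len(out), sum(r["label"] for r in out))
    return out


def evaluate(predictions: Sequence[int], truth: Sequence[int]) -> ClassificationMetrics:
    """Confusion-count metrics of binary predictions against ground truth."""
    pred = np.asarray(predictions, dtype=int)
    true = np.asarray(truth, dtype=int)
    if pred.shape != true.shape:
        raise ValueError(f"length mismatch: {pred.shape} predictions vs {true.shape} truth")
    return ClassificationMetrics(
        n_sips=int(np.sum(true == 1)),
        n_nonsips=int(np.sum(true == 0)),
        n_sips_detected=int(np.sum((true == 1) & (pred == 1))),
        n_nonsips_detected=int(np.sum((true == 0) & (pred == 0))),
    )


def accuracy_per_energy(accuracy: float, energy_mj: float) -> float:
    """Accuracy-per-energy ratio in %/mJ, for ranking architectures.

    ``energy_mj`` is a user-supplied measurement (mJ per classification).
    """
    if energy_mj <= 0:
        raise ValueError("energy_mj must be positive")
    return 100.0 * accuracy / energy_mj
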