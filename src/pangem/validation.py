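"""Model-validation metrics for qualitative and quantitative phenotype calls.

Qualitative predictions (carbon-source utilisation, auxotrophy) are scored
from a confusion matrix; which phenotype counts as "positive" depends on the
assay (growth for carbon sources, essentiality for auxotrophies), so callers
declare the polarity when building the counts rather than relying on a
hidden convention.  Quantitative predictions (growth rates) are scored by
MAPE, RMSE and the Pearson correlation.

Rate metrics (accuracy, precision, sensitivity, FPR, failure rate) are
reported in percent; the F-score on its usual 0-1 scale.  A metric whose
denominator is zero is reported as None (undefined), never as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "QuantitativeFit",
    "confusion_metrics",
    "failure_rate",
    "quantitative_metrics",
    "round_half_away",
]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (spreadsheet convention), e.g. 82.5 -> 83."""
    factor = 10**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion counts must not all be zero")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class QuantitativeFit:
    predictions: Sequence[float]
    observations: Sequence[float]

    def __post_init__(self) -> None:
        if len(self.predictions) != len(self.observations):
            raise ValueError("predictions and observations must be paired")
        if len(self.predictions) < 2:
            raise ValueError("need at least 2 pairs")
        if any(o <= 0 for o in self.observations):
            raise ValueError("observations must be positive for MAPE")


def confusion_metrics(c: ConfusionCounts) -> Dict[str, Optional[float]]:
    """Accuracy/precision/sensitivity/FPR in percent, F-score in [0, 1]."""

    def ratio(num: int, den: int) -> Optional[float]:
        return None if den == 0 else num / den

    precision = ratio(c.tp, c.tp + c.fp)
    sensitivity = ratio(c.tp, c.tp + c.fn)
    if precision is None or sensitivity is None or precision + sensitivity == 0:
        f_score: Optional[float] = None
    else:
        f_score = 2 * precision * sensitivity / (precision + sensitivity)
    fpr = ratio(c.fp, c.fp + c.tn)
    return {
        "accuracy": 100.0 * (c.tp + c.tn) / c.total,
        "precision": None if precision is None else 100.0 * precision,
        "sensitivity": None if sensitivity is None else 100.0 * sensitivity,
        "f_score": f_score,
        "fpr": None if fpr is None else 100.0 * fpr,
    }


def failure_rate(n_failed: int, n_total: int) -> float:
    """Percent of simulations with the wrong phenotype call, to one decimal."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_failed <= n_total:
        raise ValueError("n_failed must lie in [0, n_total]")
    return round_half_away(100.0 * n_failed / n_total, 1)


def quantitative_metrics(fit: QuantitativeFit) -> Dict[str, Optional[float]]:
    """MAPE (percent), RMSE (same units as the rates) and Pearson r."""
    pred = np.asarray(fit.predictions, dtype=float)
    obs = np.asarray(fit.observations, dtype=float)
    mape = 100.0 * float(np.mean(np.abs(pred - obs) / obs))
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        r: Optional[float] = None  # undefined for a constant vector
    else:
        r = float(np.corrcoef(pred, obs)[0, 1])
    return {"mape": mape, "rmse": rmse, "pearson_r": r}
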