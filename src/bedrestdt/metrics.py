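"""Epoch-level agreement statistics between two scorings.

Epochs that are non-wear or excluded in *either* sequence are dropped from
every statistic.  Undefined ratios are reported as NaN ("not applicable"),
never as 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import cohen_kappa_score

from .model import AlignmentError, LabelSequence, State, ValidationError

__all__ = [
    "ConfusionCounts",
    "confusion",
    "performance",
    "cohen_kappa",
    "overlap_coefficient",
    "overlap_from_labels",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Bedrest-positive confusion tallies over synchronized worn epochs."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _compared_mask(test: LabelSequence, reference: LabelSequence) -> np.ndarray:
    if len(test) != len(reference):
        raise AlignmentError("sequences must be synchronized and equal length")
    return test.worn & reference.worn


def confusion(test: LabelSequence, reference: LabelSequence) -> ConfusionCounts:
    """TP/TN/FP/FN with bedrest as the positive state."""
    mask = _compared_mask(test, reference)
    t = test.states[mask] == int(State.BEDREST)
    r = reference.states[mask] == int(State.BEDREST)
    return ConfusionCounts(
        tp=int((t & r).sum()),
        tn=int((~t & ~r).sum()),
        fp=int((t & ~r).sum()),
        fn=int((~t & r).sum()),
    )


def performance(c: ConfusionCounts) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) = (TP/(TP+FN), TN/(TN+FP), (TP+TN)/total)."""
    if c.total == 0:
        raise ValidationError("no compared epochs: all non-wear/excluded")
    sensitivity = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else math.nan
    specificity = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else math.nan
    accuracy = (c.tp + c.tn) / c.total
    return sensitivity, specificity, accuracy


def cohen_kappa(a: LabelSequence, b: LabelSequence, weighting: str | None = None) -> float:
    """Cohen's kappa over compared epochs.

    ``weighting`` may be None, 'linear' or 'quadratic'; for two-state
    sequences all three coincide.  Two identical constant sequences are
    total agreement with degenerate marginals (the formula is 0/0) and are
    reported as 1.0 with a warning.
    """
    mask = _compared_mask(a, b)
    xa, xb = a.states[mask], b.states[mask]
    if len(xa) == 0:
        raise ValidationError("no compared epochs: all non-wear/excluded")
    if np.array_equal(xa, xb) and len(np.unique(xa)) == 1:
        warnings.warn("identical constant sequences: kappa reported as 1.0", stacklevel=2)
        return 1.0
    return float(cohen_kappa_score(xa, xb, weights=weighting))


def overlap_coefficient(a_bedrest: np.ndarray, b_bedrest: np.ndarray) -> float:
    """Agreed bedrest time divided by the smaller method total.

    Inputs are boolean per-epoch bedrest masks on a shared timeline.  If
    either mask is empty the coefficient is not applicable (NaN).  Equals
    1.0 whenever one bedrest set is a subset of the other.
    """
    a = np.asarray(a_bedrest, dtype=bool)
    b = np.asarray(b_bedrest, dtype=bool)
    if a.shape != b.shape:
        raise AlignmentError("bedrest masks must share one timeline")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 or nb == 0:
        return math.nan
    return float((a & b).sum() / min(na, nb))


def overlap_from_labels(a: LabelSequence, b: LabelSequence) -> float:
    """Overlap coefficient of two scorings' bedrest sets over compared epochs."""
    mask = _compared_mask(a, b)
    return overlap_coefficient(
        (a.states == int(State.BEDREST)) & mask,
        (b.states == int(State.BEDREST)) & mask,
    )
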