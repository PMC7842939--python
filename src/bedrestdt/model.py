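"""Core data model for minute-epoch actigraphy.

An :class:`EpochSeries` holds triaxial ActiGraph-style activity counts on a
gap-free, fixed-step time grid; the vector magnitude (VM) of each epoch is
the Euclidean norm of the three per-axis counts.  A :class:`LabelSequence`
assigns exactly one state per epoch (bedrest / wake / non-wear / excluded),
and an :class:`Episode` is one maximal run of a single state.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "State",
    "EpochSeries",
    "LabelSequence",
    "Episode",
    "AlignmentError",
    "ValidationError",
    "FormatError",
    "ConfigurationError",
    "compute_vector_magnitude",
    "reintegrate",
    "episodes_from_labels",
]


class AlignmentError(ValueError):
    """Two per-epoch sequences that must be synchronized have different lengths."""


class ValidationError(ValueError):
    """Input data violate a model invariant (negative counts, gaps, ...)."""


class FormatError(ValueError):
    """A file could not be parsed in the declared dialect."""


class ConfigurationError(ValueError):
    """Parameters are inconsistent with the data or with each other."""


class State(enum.IntEnum):
    """Per-epoch classification state."""

    BEDREST = 0
    WAKE = 1
    NONWEAR = 2
    EXCLUDED = 3

    @property
    def token(self) -> str:
        return self.name.lower()

    @classmethod
    def from_token(cls, token: str) -> "State":
        try:
            return cls[token.strip().upper()]
        except KeyError:
            raise ValidationError(f"unknown state token: {token!r}") from None


def compute_vector_magnitude(axis1, axis2, axis3) -> np.ndarray:
    """Per-epoch vector magnitude: element-wise Euclidean norm of the axes.

    The result is never rounded; threshold comparisons downstream operate on
    the real value.
    """
    a1 = np.asarray(axis1, dtype=float)
    a2 = np.asarray(axis2, dtype=float)
    a3 = np.asarray(axis3, dtype=float)
    if not (a1.shape == a2.shape == a3.shape) or a1.ndim != 1:
        raise AlignmentError("axis count vectors must be 1-D and equal length")
    if (a1 < 0).any() or (a2 < 0).any() or (a3 < 0).any():
        raise ValidationError("activity counts must be non-negative")
    return np.sqrt(a1 * a1 + a2 * a2 + a3 * a3)


@dataclass
class EpochSeries:
    """Gap-free triaxial activity-count series at a fixed epoch length.

    Parameters
    ----------
    start_time
        Timestamp of the first epoch's start instant.
    axis1, axis2, axis3
        Per-epoch activity counts (non-negative integers).
    epoch_length
        Epoch duration in seconds (default 60).
    vm
        Per-epoch vector magnitude.  Recomputed from the axes when omitted.
    meta
        Free-form device/subject annotations.
    """

    start_time: datetime
    axis1: np.ndarray
    axis2: np.ndarray
    axis3: np.ndarray
    epoch_length: int = 60
    vm: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis1 = np.asarray(self.axis1, dtype=np.int64)
        self.axis2 = np.asarray(self.axis2, dtype=np.int64)
        self.axis3 = np.asarray(self.axis3, dtype=np.int64)
        if not (len(self.axis1) == len(self.axis2) == len(self.axis3)):
            raise AlignmentError("axis count vectors must have equal length")
        if len(self.axis1) < 1:
            raise ValidationError("an EpochSeries needs at least one epoch")
        if int(self.epoch_length) <= 0:
            raise ConfigurationError("epoch_length must be a positive integer")
        self.epoch_length = int(self.epoch_length)
        if min(self.axis1.min(), self.axis2.min(), self.axis3.min()) < 0:
            raise ValidationError("activity counts must be non-negative")
        vm = compute_vector_magnitude(self.axis1, self.axis2, self.axis3)
        if self.vm is None:
            self.vm = vm
        else:
            self.vm = np.asarray(self.vm, dtype=float)
            if len(self.vm) != len(self.axis1):
                raise AlignmentError("vm must align with the axis vectors")
            if np.max(np.abs(self.vm - vm)) > 1e-9:
                raise ValidationError("vm inconsistent with axis counts")

    def __len__(self) -> int:
        return len(self.axis1)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        """Start instant of every epoch."""
        return pd.date_range(
            self.start_time, periods=len(self), freq=pd.Timedelta(seconds=self.epoch_length)
        )

    def signal(self, name: str = "vm") -> np.ndarray:
        """Return the per-epoch counts used for scoring (``vm`` or an axis)."""
        if name not in ("vm", "axis1", "axis2", "axis3"):
            raise ConfigurationError(f"unknown signal {name!r}")
        return getattr(self, name)

    def time_of(self, index: int) -> datetime:
        return self.start_time + timedelta(seconds=index * self.epoch_length)


@dataclass
class LabelSequence:
    """One :class:`State` per epoch, aligned to an :class:`EpochSeries`."""

    states: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.ndim != 1 or len(self.states) < 1:
            raise ValidationError("states must be a non-empty 1-D vector")
        if not np.isin(self.states, [int(s) for s in State]).all():
            raise ValidationError("states contain values outside the State enum")

    def __len__(self) -> int:
        return len(self.states)

    def __eq__(self, other) -> bool:  # value semantics for tests
        return isinstance(other, LabelSequence) and np.array_equal(self.states, other.states)

    @classmethod
    def filled(cls, n: int, state: State = State.WAKE) -> "LabelSequence":
        return cls(np.full(n, int(state), dtype=np.int8))

    @classmethod
    def from_tokens(cls, tokens: Iterable[str]) -> "LabelSequence":
        return cls(np.array([int(State.from_token(t)) for t in tokens], dtype=np.int8))

    def to_tokens(self) -> list[str]:
        return [State(s).token for s in self.states]

    def mask(self, *states: State) -> np.ndarray:
        return np.isin(self.states, [int(s) for s in states])

    @property
    def worn(self) -> np.ndarray:
        """Epochs that enter scoring and agreement statistics."""
        return ~self.mask(State.NONWEAR, State.EXCLUDED)

    def copy(self) -> "LabelSequence":
        return LabelSequence(self.states.copy())


@dataclass(frozen=True)
class Episode:
    """Maximal run of one state over half-open epoch indices [start, end)."""

    state: State
    start_index: int
    end_index: int
    epoch_length: int = 60

    def __post_init__(self) -> None:
        if self.start_index >= self.end_index:
            raise ValidationError("episode must contain at least one epoch")

    @property
    def n_epochs(self) -> int:
        return self.end_index - self.start_index

    @property
    def duration_min(self) -> float:
        return self.n_epochs * self.epoch_length / 60.0


def episodes_from_labels(labels: LabelSequence, epoch_length: int = 60) -> list[Episode]:
    """Tile a label sequence into maximal single-state episodes."""
    states = labels.states
    changes = np.flatnonzero(np.diff(states)) + 1
    bounds = np.concatenate(([0], changes, [len(states)]))
    return [
        Episode(State(int(states[lo])), int(lo), int(hi), epoch_length)
        for lo, hi in zip(bounds[:-1], bounds[1:])
    ]


def reintegrate(series: EpochSeries, target_epoch: int) -> EpochSeries:
    """Re-integrate a series to a coarser epoch length.

    Per-axis counts are summed within each target window and the vector
    magnitude is recomputed from the summed axes (norm of sums, not sum of
    norms).  A trailing partial window is dropped with a warning because a
    short tail would bias downstream block averages.
    """
    target_epoch = int(target_epoch)
    if target_epoch <= 0 or target_epoch % series.epoch_length != 0:
        raise ConfigurationError(
            f"target epoch {target_epoch}s must be a positive multiple of "
            f"the source epoch {series.epoch_length}s"
        )
    ratio = target_epoch // series.epoch_length
    if ratio == 1:
        return EpochSeries(
            start_time=series.start_time,
            axis1=series.axis1.copy(),
            axis2=series.axis2.copy(),
            axis3=series.axis3.copy(),
            epoch_length=series.epoch_length,
            meta=dict(series.meta),
        )
    n_full = len(series) // ratio
    if n_full == 0:
        raise ConfigurationError("series shorter than one target window")
    if len(series) % ratio:
        warnings.warn(
            f"dropping {len(series) - n_full * ratio} trailing source epochs "
            f"(partial {target_epoch}s window)",
            stacklevel=2,
        )

    def fold(a: np.ndarray) -> np.ndarray:
        return a[: n_full * ratio].reshape(n_full, ratio).sum(axis=1)

    return EpochSeries(
        start_time=series.start_time,
        axis1=fold(series.axis1),
        axis2=fold(series.axis2),
        axis3=fold(series.axis3),
        epoch_length=target_epoch,
        meta=dict(series.meta),
    )
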