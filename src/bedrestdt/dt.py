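"""Four-step decision tree labeling every worn epoch BEDREST or WAKE.

The detector coarse-classifies a recording with block averages and then
pinpoints transitions with per-epoch triggers:

1. Partition the worn segment into consecutive blocks of ``block_length``
   epochs (the trailing partial block is averaged over its own epochs) and
   set the initial status from the first block's mean: <= ``threshold`` is
   bedrest, above it is wake.
2. While wake, scan forward for the first block whose mean is strictly
   below the threshold; within that block and the preceding one, the epoch
   after the *last* two consecutive epochs above ``bedrest_start_trigger``
   is bedrest-start.
3. While bedrest, scan forward for the first block whose mean is strictly
   above the threshold; within that block and the preceding one, the epoch
   before the *first* two consecutive epochs above ``bedrest_end_trigger``
   is bedrest-end.
4. After the start/end cycle exhausts the segment, bedrest episodes shorter
   than ``min_bedrest_min`` are relabeled wake.

When no trigger pair exists in the two-block search window, the boundary
falls back to the identified block's first epoch (clamped so boundaries
never move backwards).  Epochs after the last identified change keep the
current status.  Default parameters are the values calibrated for
preschool children: block length 36 epochs, threshold 230 counts/min,
start trigger 305, end trigger 1129, minimum bedrest 30 min.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    AlignmentError,
    ConfigurationError,
    EpochSeries,
    Episode,
    LabelSequence,
    State,
    episodes_from_labels,
)
from .segments import worn_segments

__all__ = [
    "DTParams",
    "partition_blocks",
    "initial_status",
    "find_bedrest_start",
    "find_bedrest_end",
    "detect_bedrest",
]


@dataclass(frozen=True)
class DTParams:
    """Tunable decision-tree parameters (counts/min scale, 60-s epochs)."""

    block_length: int = 36
    threshold: float = 230.0
    bedrest_start_trigger: float = 305.0
    bedrest_end_trigger: float = 1129.0
    min_bedrest_min: int = 30

    def __post_init__(self) -> None:
        if int(self.block_length) < 2:
            raise ConfigurationError("block_length must be >= 2 epochs")
        if min(self.threshold, self.bedrest_start_trigger, self.bedrest_end_trigger) < 0:
            raise ConfigurationError("threshold and triggers must be non-negative")
        if self.min_bedrest_min < 0:
            raise ConfigurationError("min_bedrest_min must be non-negative")
        object.__setattr__(self, "block_length", int(self.block_length))


def partition_blocks(x: np.ndarray, block_length: int) -> np.ndarray:
    """Mean counts/epoch of consecutive non-overlapping blocks.

    The final partial block is averaged over the epochs it actually has.
    """
    n = len(x)
    if n == 0:
        return np.empty(0)
    starts = np.arange(0, n, block_length)
    sums = np.add.reduceat(np.asarray(x, dtype=float), starts)
    sizes = np.minimum(starts + block_length, n) - starts
    return sums / sizes


def initial_status(first_block_mean: float, threshold: float) -> State:
    """Block mean <= threshold starts the recording in bedrest, else wake."""
    return State.BEDREST if first_block_mean <= threshold else State.WAKE


def _pair_indices(x: np.ndarray, lo: int, hi: int, trigger: float) -> np.ndarray:
    """Indices i in [lo, hi-1) with x[i] and x[i+1] both strictly above trigger."""
    if hi - lo < 2:
        return np.empty(0, dtype=int)
    window = x[lo:hi]
    above = window > trigger
    return lo + np.flatnonzero(above[:-1] & above[1:])


def _search_window(block: int, block_length: int, pos: int, n: int) -> tuple[int, int]:
    """Two-block trigger search window, clamped to [pos, n)."""
    lo = (block - 1) * block_length if block >= 1 else 0
    return max(lo, pos), min((block + 1) * block_length, n)


def find_bedrest_start(
    x: np.ndarray, block_means: np.ndarray, from_epoch: int, params: DTParams
) -> int | None:
    """Bedrest-start epoch index at or after ``from_epoch``, or None.

    Returns None when no remaining block mean is below the threshold
    ("no further bedrest").
    """
    L = params.block_length
    for k in range(from_epoch // L, len(block_means)):
        if block_means[k] < params.threshold:
            lo, hi = _search_window(k, L, from_epoch, len(x))
            pairs = _pair_indices(x, lo, hi, params.bedrest_start_trigger)
            if len(pairs):
                return int(pairs[-1]) + 2
            return max(k * L, from_epoch)  # fallback: first epoch of the block
    return None


def find_bedrest_end(
    x: np.ndarray, block_means: np.ndarray, from_epoch: int, params: DTParams
) -> int | None:
    """First wake epoch (the one after bedrest-end) at or after ``from_epoch``.

    Returns None when no remaining block mean is above the threshold
    (bedrest to the end of the segment).
    """
    L = params.block_length
    for k in range(from_epoch // L, len(block_means)):
        if block_means[k] > params.threshold:
            lo, hi = _search_window(k, L, from_epoch, len(x))
            pairs = _pair_indices(x, lo, hi, params.bedrest_end_trigger)
            if len(pairs):
                return int(pairs[0])  # bedrest-end is pairs[0] - 1
            return max(k * L, from_epoch)
    return None


def _label_segment(x: np.ndarray, params: DTParams) -> np.ndarray:
    n = len(x)
    seg = np.empty(n, dtype=np.int8)
    block_means = partition_blocks(x, params.block_length)
    status = initial_status(block_means[0], params.threshold)
    pos = 0
    seen: set[tuple[int, int]] = set()
    while pos < n:
        key = (int(status), pos)
        if key in seen:
            # Degenerate parameter combinations (e.g. end trigger below the
            # start trigger) can cycle without advancing; label one epoch
            # with the current status and move on.  Deterministic guard.
            seg[pos] = int(status)
            pos += 1
            continue
        seen.add(key)
        if status == State.WAKE:
            s = find_bedrest_start(x, block_means, pos, params)
            if s is None:
                seg[pos:] = int(State.WAKE)
                break
            seg[pos:s] = int(State.WAKE)
            pos, status = s, State.BEDREST
        else:
            e = find_bedrest_end(x, block_means, pos, params)
            if e is None:
                seg[pos:] = int(State.BEDREST)
                break
            seg[pos:e] = int(State.BEDREST)
            pos, status = e, State.WAKE
    return seg


def _demote_short_bedrest(seg: np.ndarray, min_epochs: int) -> None:
    labels = LabelSequence(seg) if len(seg) else None
    if labels is None:
        return
    for ep in episodes_from_labels(labels):
        if ep.state == State.BEDREST and ep.n_epochs < min_epochs:
            seg[ep.start_index : ep.end_index] = int(State.WAKE)


def detect_bedrest(
    series: EpochSeries,
    params: DTParams = DTParams(),
    nonwear: LabelSequence | None = None,
    signal: str = "vm",
) -> tuple[LabelSequence, list[Episode]]:
    """Label every worn epoch BEDREST or WAKE and return the tiled episodes.

    Segments separated by non-wear/excluded runs are processed
    independently: blocks never span a non-wear gap, and the minimum
    bedrest duration (step 4) is enforced once per segment after the
    start/end cycle completes.
    """
    if series.epoch_length != 60:
        raise ConfigurationError("the decision tree is defined on 60-s epochs")
    if nonwear is not None and len(nonwear) != len(series):
        raise AlignmentError("nonwear labels must align with the series")
    x_all = series.signal(signal)
    out = (
        nonwear.copy() if nonwear is not None else LabelSequence.filled(len(series), State.WAKE)
    )
    min_epochs = int(round(params.min_bedrest_min * 60 / series.epoch_length))
    for lo, hi in worn_segments(out):
        seg = _label_segment(x_all[lo:hi], params)
        _demote_short_bedrest(seg, min_epochs)
        out.states[lo:hi] = seg
    return out, episodes_from_labels(out, series.epoch_length)
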