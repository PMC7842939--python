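"""Non-wear detection for minute-epoch counts (Choi-style zero-run rule).

A non-wear interval is a run of at least ``window_min`` consecutive
zero-count minutes.  Short artifactual spikes of up to
``spike_tolerance_min`` consecutive non-zero minutes are tolerated inside
the window provided they are flanked by at least ``spike_flank_min`` zero
minutes on both sides; tolerated spike minutes are flagged as non-wear
together with the surrounding zeros.  Defaults (90 / 2 / 30) follow the
published algorithm's standard settings for waist-worn devices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ConfigurationError, EpochSeries, LabelSequence, State

__all__ = ["NonwearParams", "detect_nonwear"]


@dataclass(frozen=True)
class NonwearParams:
    window_min: int = 90
    spike_tolerance_min: int = 2
    spike_flank_min: int = 30
    signal: str = "vm"

    def __post_init__(self) -> None:
        if min(self.window_min, self.spike_tolerance_min, self.spike_flank_min) <= 0:
            raise ConfigurationError("all non-wear durations must be positive")
        if self.spike_tolerance_min >= self.window_min:
            raise ConfigurationError("spike tolerance must be shorter than the window")


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index ranges of maximal True runs."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def detect_nonwear(series: EpochSeries, params: NonwearParams = NonwearParams()) -> LabelSequence:
    """Flag non-wear epochs; all other epochs are provisionally WAKE.

    The tested signal is ``params.signal`` (vm by default; a zero vm means
    all three axes are zero, so the definitions coincide).  Requires 60-s
    epochs — re-integrate finer data first.
    """
    if series.epoch_length != 60:
        raise ConfigurationError(
            f"non-wear detection is defined on 60-s epochs, got {series.epoch_length}s; "
            "re-integrate the series first"
        )
    x = series.signal(params.signal)
    zero = x == 0
    zero_runs = _runs(zero)

    # Merge zero runs across tolerated spikes: a gap of nonzero minutes of
    # length <= spike_tolerance_min joins its neighbours when both flanking
    # zero runs are >= spike_flank_min long.
    merged: list[list[int]] = []  # [start, end) candidate intervals
    for start, end in zero_runs:
        if merged:
            prev = merged[-1]
            gap = start - prev[1]
            if (
                gap <= params.spike_tolerance_min
                and prev[1] - prev[0] >= params.spike_flank_min
                and end - start >= params.spike_flank_min
            ):
                prev[1] = end
                continue
        merged.append([start, end])

    labels = LabelSequence.filled(len(series), State.WAKE)
    for start, end in merged:
        if end - start >= params.window_min:
            labels.states[start:end] = int(State.NONWEAR)
    return labels
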