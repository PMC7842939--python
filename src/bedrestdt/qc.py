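"""Recording-validity rules for multi-day preschool accelerometer wear.

A *night* is the window 22:00 of a calendar date through 06:59 the next
morning; it is valid when at least 6 hours (360 minutes, inclusive) of worn
epochs fall inside it.  A recording is analyzable when it has >= 3 valid
nights, of which >= 2 are weeknights and >= 1 a weekend night (a night is a
weekend night when its 22:00 start falls on Friday or Saturday).  Data
after a sustained (>= 48 h) non-wear run are excluded outright.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, time, timedelta

import numpy as np

from .model import AlignmentError, EpochSeries, LabelSequence, State, episodes_from_labels

__all__ = ["ValidityReport", "is_valid_night", "truncate_after_nonwear", "validate_recording"]

NIGHT_START = time(22, 0)
NIGHT_MINUTES = 9 * 60  # 22:00 .. 06:59 next day
MIN_WORN_MINUTES = 360
WEEKEND_START_WEEKDAYS = (4, 5)  # Friday, Saturday


@dataclass(frozen=True)
class ValidityReport:
    valid_nights: int
    weeknights: int
    weekend_nights: int
    truncated_at: int | None
    is_valid: bool

    def to_dict(self) -> dict:
        return {
            "valid_nights": self.valid_nights,
            "weeknights": self.weeknights,
            "weekend_nights": self.weekend_nights,
            "truncated_at": self.truncated_at,
            "is_valid": self.is_valid,
        }


def _window_indices(series: EpochSeries, start: datetime, minutes: int) -> tuple[int, int]:
    """Clip a wall-clock window to the series' epoch index range."""
    step = series.epoch_length
    lo = int(np.ceil((start - series.start_time).total_seconds() / step))
    hi = int(np.ceil(((start + timedelta(minutes=minutes)) - series.start_time).total_seconds() / step))
    return max(lo, 0), min(hi, len(series))


def is_valid_night(series: EpochSeries, nonwear_labels: LabelSequence, night_date: date) -> bool:
    """True iff worn epochs within 22:00 night_date .. 06:59 next day total >= 360 min.

    Epochs outside the recording's coverage count as not worn; the worn
    total need not be contiguous.
    """
    if len(nonwear_labels) != len(series):
        raise AlignmentError("labels must align with the series")
    lo, hi = _window_indices(series, datetime.combine(night_date, NIGHT_START), NIGHT_MINUTES)
    if hi <= lo:
        return False
    worn = nonwear_labels.worn[lo:hi]
    worn_minutes = worn.sum() * series.epoch_length / 60.0
    return bool(worn_minutes >= MIN_WORN_MINUTES)


def truncate_after_nonwear(
    series: EpochSeries, nonwear_labels: LabelSequence, limit_h: float = 48.0
) -> tuple[LabelSequence, int | None]:
    """Mark everything after the first non-wear run of >= limit_h as EXCLUDED.

    Returns the updated labels and the epoch index at which truncation took
    effect (the first epoch after the run), or None if no run qualifies.
    """
    if len(nonwear_labels) != len(series):
        raise AlignmentError("labels must align with the series")
    limit_epochs = limit_h * 3600.0 / series.epoch_length
    out = nonwear_labels.copy()
    for ep in episodes_from_labels(nonwear_labels, series.epoch_length):
        if ep.state == State.NONWEAR and ep.n_epochs >= limit_epochs:
            cut = ep.end_index
            if cut < len(out):
                out.states[cut:] = int(State.EXCLUDED)
            return out, cut
    return out, None


def validate_recording(series: EpochSeries, nonwear_labels: LabelSequence) -> ValidityReport:
    """Apply the 48-h truncation, then aggregate night validity over the recording."""
    labels, truncated_at = truncate_after_nonwear(series, nonwear_labels)
    first_night = (series.start_time - timedelta(hours=7)).date()
    last_night = (series.start_time + timedelta(seconds=len(series) * series.epoch_length)).date()
    weeknights = weekend_nights = 0
    night = first_night
    while night <= last_night:
        if is_valid_night(series, labels, night):
            if night.weekday() in WEEKEND_START_WEEKDAYS:
                weekend_nights += 1
            else:
                weeknights += 1
        night += timedelta(days=1)
    valid_nights = weeknights + weekend_nights
    return ValidityReport(
        valid_nights=valid_nights,
        weeknights=weeknights,
        weekend_nights=weekend_nights,
        truncated_at=truncated_at,
        is_valid=(valid_nights >= 3 and weeknights >= 2 and weekend_nights >= 1),
    )
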