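"""Shared helper: maximal worn segments of a label sequence."""

from __future__ import annotations

import numpy as np

from .model import LabelSequence

__all__ = ["worn_segments"]


def worn_segments(labels: LabelSequence) -> list[tuple[int, int]]:
    """Half-open [start, end) ranges of maximal worn (non-NONWEAR/EXCLUDED) runs.

    Scorers process each worn segment independently so that bedrest
    episodes and block averages never span a non-wear gap.
    """
    worn = labels.worn
    if not worn.any():
        return []
    padded = np.concatenate(([False], worn, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))
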