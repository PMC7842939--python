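import sys
from datetime import datetime
from pathlib import Path

import numpy as np
import pytest

from bedrestdt import EpochSeries

sys.path.insert(0, str(Path(__file__).parent))  # reference_dt oracle

START = datetime(2022, 3, 7, 0, 0)  # a Monday at midnight


def flat_series(counts, start=START, epoch_length=60) -> EpochSeries:
    """Series whose vm equals the given counts (all on axis1)."""
    counts = np.asarray(np.round(counts), dtype=np.int64)
    zeros = np.zeros_like(counts)
    return EpochSeries(start, counts, zeros, zeros, epoch_length=epoch_length)


@pytest.fixture
def rng():
    return np.random.default_rng(20220307)


@pytest.fixture
def make_flat_series():
    return flat_series
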