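import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from nirsentropy.oximetry import BASELINE_SAMPLES, Rso2Series


def make_series(intraop, baseline_value: float = 73.4, subject_id: str = "T001") -> Rso2Series:
    """Assemble a valid series from an intraop trace and a constant baseline."""
    intraop = np.asarray(intraop, dtype=float)
    values = np.concatenate([np.full(BASELINE_SAMPLES, baseline_value), intraop])
    return Rso2Series(
        subject_id=subject_id,
        values=values,
        baseline_window=(0, BASELINE_SAMPLES),
        intraop_window=(BASELINE_SAMPLES, BASELINE_SAMPLES + intraop.size),
    )


@pytest.fixture
def series_factory():
    return make_series


@pytest.fixture
def rng():
    return np.random.default_rng(20220929)
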