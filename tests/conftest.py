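import datetime as dt

import numpy as np
import pytest

from ontosleep import dam_io


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def make_matrix(
    counts: np.ndarray,
    start: dt.datetime = dt.datetime(2026, 1, 5, 6, 0),
    status: np.ndarray | None = None,
) -> dam_io.ActivityMatrix:
    counts = np.asarray(counts)
    n = counts.shape[0]
    return dam_io.ActivityMatrix(
        timestamps=dam_io.make_timestamps(start, n),
        counts=counts,
        status=np.ones(n, dtype=np.int64) if status is None else status,
    )


@pytest.fixture
def matrix_factory():
    return make_matrix
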