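import warnings

import numpy as np
import pytest

from drpscreen import synth
from drpscreen.data_model import ResponseMatrix

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def default_truth():
    """The default synthetic study: 200 lines x 100 drugs, 5 factors."""
    m, truth = synth.simulate_response_matrix(seed=11)
    return m, truth


@pytest.fixture
def small_matrix():
    """A tiny fully observed response matrix with hand-set values."""
    rng = np.random.default_rng(7)
    vals = 5.5 + rng.standard_normal((8, 5))
    return ResponseMatrix(
        [f"L{i}" for i in range(8)], [f"D{j}" for j in range(5)],
        vals, np.ones_like(vals, dtype=bool),
    )


def make_matrix(vals, cells=None, drugs=None):
    vals = np.asarray(vals, dtype=float)
    cells = cells or [f"L{i}" for i in range(vals.shape[0])]
    drugs = drugs or [f"D{j}" for j in range(vals.shape[1])]
    return ResponseMatrix(cells, drugs, vals, np.isfinite(vals))
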