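import numpy as np
import pandas as pd
import pytest

from tracelfq import IonTable, IntensityTrace, TraceSet


def make_trace_set(matrix, ids=None):
    matrix = np.asarray(matrix, dtype=float)
    if ids is None:
        ids = [f"T{i}" for i in range(matrix.shape[0])]
    return TraceSet.from_matrix(matrix, ids)


def fuzz_trace_set(rng, n_traces=None, n_features=None, missing_p=0.3):
    """Random TraceSet with scattered missingness for oracle comparisons."""
    n = n_traces or int(rng.integers(2, 9))
    f = n_features or int(rng.integers(3, 12))
    mat = rng.normal(20, 3, size=(n, f))
    mat[rng.random((n, f)) < missing_p] = np.nan
    return make_trace_set(mat)


@pytest.fixture
def toy_table():
    """Two proteins, three ions, three samples; one missing record."""
    rows = [
        ("P1", "pepA|2", "s1", 100.0), ("P1", "pepA|2", "s2", 200.0),
        ("P1", "pepA|2", "s3", 400.0),
        ("P1", "pepB|3", "s1", 10.0), ("P1", "pepB|3", "s2", 20.0),
        ("P2", "pepC|2", "s1", 50.0), ("P2", "pepC|2", "s2", 50.0),
        ("P2", "pepC|2", "s3", 50.0),
    ]
    return IonTable(pd.DataFrame(
        rows, columns=["protein", "ion", "sample", "intensity"]))
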