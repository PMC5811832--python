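import numpy as np
import pytest

from wavegraph.types import BinaryGraph, ConnectivityMatrix


@pytest.fixture
def k4() -> BinaryGraph:
    a = np.ones((4, 4), int) - np.eye(4, dtype=int)
    return BinaryGraph(adjacency=a, density=1.0)


@pytest.fixture
def star4() -> BinaryGraph:
    a = np.zeros((4, 4), int)
    a[0, 1:] = 1
    return BinaryGraph(adjacency=a + a.T, density=0.5)


@pytest.fixture
def cycle4() -> BinaryGraph:
    a = np.zeros((4, 4), int)
    for i in range(4):
        a[i, (i + 1) % 4] = 1
    return BinaryGraph(adjacency=((a + a.T) > 0).astype(int), density=0.5)


def edge_rows_to_matrices(rows: np.ndarray, n_rois: int) -> list[ConnectivityMatrix]:
    """Turn (n_subjects, n_edges) 'z-scale' rows into connectivity matrices
    (tanh keeps entries in (-1, 1); arctanh in the pipeline undoes it)."""
    iu, ju = np.triu_indices(n_rois, 1)
    mats = []
    for row in rows:
        m = np.zeros((n_rois, n_rois))
        m[iu, ju] = np.tanh(row)
        m += m.T
        np.fill_diagonal(m, 1.0)
        mats.append(ConnectivityMatrix(values=m, scale=2))
    return mats
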