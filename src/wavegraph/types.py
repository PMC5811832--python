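"""Core containers shared across the pipeline.

These are light dataclass wrappers around numpy arrays / pandas frames that
carry the metadata (sampling interval, ROI labels, subject/session ids)
needed to keep a multi-subject, multi-session analysis auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np


def default_roi_labels(n_rois: int) -> tuple[str, ...]:
    """AAL-style numbered labels: ROI_001 ... ROI_NNN."""
    return tuple(f"ROI_{i + 1:03d}" for i in range(n_rois))


@dataclass
class RoiTimeSeries:
    """One subject-session's regional mean BOLD signal.

    values : (timepoints, rois) float array, no missing values.
    tr     : sampling interval in seconds.
    """

    values: np.ndarray
    tr: float
    roi_labels: tuple[str, ...] = ()
    subject: str = ""
    session: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D (timepoints x rois) array")
        if self.values.shape[0] < 2:
            raise ValueError("time series needs at least 2 timepoints")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")
        if self.tr <= 0:
            raise ValueError("tr must be positive (seconds)")
        if not self.roi_labels:
            self.roi_labels = default_roi_labels(self.values.shape[1])
        if len(self.roi_labels) != self.values.shape[1]:
            raise ValueError("roi_labels length does not match number of columns")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric ROI x ROI wavelet-correlation matrix at one scale."""

    values: np.ndarray
    scale: int
    roi_labels: tuple[str, ...] = ()
    subject: str = ""
    session: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        r, c = self.values.shape
        if r != c:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if np.nanmax(np.abs(self.values)) > 1 + 1e-9:
            raise ValueError("correlations must lie in [-1, 1]")
        if not self.roi_labels:
            self.roi_labels = default_roi_labels(r)

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class EdgeSet:
    """Unordered, de-duplicated ROI index pairs (i < j)."""

    pairs: tuple[tuple[int, int], ...]

    def __init__(self, pairs: Iterable[Sequence[int]]):
        norm = []
        seen = set()
        for i, j in pairs:
            i, j = int(i), int(j)
            if i == j:
                raise ValueError(f"self-pair ({i}, {j}) not allowed")
            if i > j:
                i, j = j, i
            if (i, j) in seen:
                raise ValueError(f"duplicate edge ({i}, {j})")
            seen.add((i, j))
            norm.append((i, j))
        object.__setattr__(self, "pairs", tuple(norm))

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def __contains__(self, pair) -> bool:
        i, j = pair
        return (min(i, j), max(i, j)) in set(self.pairs)

    def max_index(self) -> int:
        return max(j for _, j in self.pairs) if self.pairs else -1


@dataclass
class BinaryGraph:
    """Unweighted, undirected graph at a fixed edge density.

    adjacency : (rois, rois) 0/1 symmetric int array, zero diagonal.
    density   : the requested edge-density fraction.
    """

    adjacency: np.ndarray
    density: float
    roi_labels: tuple[str, ...] = ()
    subject: str = ""
    session: str = ""
    edge_list: EdgeSet = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency must have zero diagonal")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be 0/1")
        self.adjacency = a.astype(np.int8)
        if not self.roi_labels:
            self.roi_labels = default_roi_labels(a.shape[0])
        if self.edge_list is None:
            ii, jj = np.nonzero(np.triu(a, 1))
            self.edge_list = EdgeSet(zip(ii.tolist(), jj.tolist()))

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return len(self.edge_list)
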