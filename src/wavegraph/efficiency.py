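"""Global, local, and nodal efficiency of binary graphs.

Efficiency metrics are averages of inverse shortest-path lengths, with
unreachable pairs contributing 0 — the convention that keeps the metrics
well defined on the fragmented graphs that a sparse (5 %) density
threshold can produce, which is why efficiency rather than raw path
length is the metric of choice at that density.

Definitions (N nodes, d_ij the unweighted shortest-path length):

    E_glob        = 1/(N(N-1)) * sum_{i != j} 1/d_ij
    E_nodal(i)    = 1/(N-1)    * sum_{j != i} 1/d_ij
    E_loc(i)      = E_glob of the subgraph induced by i's neighbours
                    (0 when i has fewer than 2 neighbours)
    E_loc(network)= mean_i E_loc(i)

E_loc(i) is the clustering-like, fault-tolerance measure used for
per-node group comparisons; E_nodal(i) is the node's mean inverse
distance to the rest of the network.  Both are emitted because "nodal
efficiency" is used for either in the connectomics literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .types import BinaryGraph


def _inverse_distance_matrix(adjacency: np.ndarray) -> np.ndarray:
    """1/d_ij for all pairs (0 on the diagonal and for unreachable pairs)."""
    n = adjacency.shape[0]
    if adjacency.sum() == 0:
        return np.zeros((n, n))
    d = shortest_path(csr_matrix(adjacency), method="D", unweighted=True, directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv


def global_efficiency(g: BinaryGraph | np.ndarray) -> float:
    """Mean inverse shortest-path length over all ordered node pairs."""
    adj = g.adjacency if isinstance(g, BinaryGraph) else np.asarray(g)
    n = adj.shape[0]
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    return float(_inverse_distance_matrix(adj).sum() / (n * (n - 1)))


def nodal_global_efficiency(g: BinaryGraph | np.ndarray) -> np.ndarray:
    """Per-node mean inverse distance to every other node."""
    adj = g.adjacency if isinstance(g, BinaryGraph) else np.asarray(g)
    n = adj.shape[0]
    if n < 2:
        raise ValueError("nodal efficiency needs at least 2 nodes")
    return _inverse_distance_matrix(adj).sum(axis=1) / (n - 1)


def local_efficiency(g: BinaryGraph | np.ndarray) -> tuple[float, np.ndarray]:
    """Network local efficiency and the per-node vector it averages.

    The nodal value for node i is the global efficiency of the subgraph
    induced by i's neighbours; nodes of degree < 2 contribute 0.
    """
    adj = g.adjacency if isinstance(g, BinaryGraph) else np.asarray(g)
    n = adj.shape[0]
    if n < 2:
        raise ValueError("local efficiency needs at least 2 nodes")
    nodal = np.zeros(n)
    for i in range(n):
        nbrs = np.nonzero(adj[i])[0]
        if nbrs.size < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        nodal[i] = global_efficiency(sub)
    return float(nodal.mean()), nodal


@dataclass
class EfficiencyResult:
    """All efficiency metrics for one subject-session graph."""

    global_efficiency: float
    local_efficiency: float
    nodal_local_efficiency: np.ndarray
    nodal_global_efficiency: np.ndarray
    subject: str = ""
    session: str = ""
    roi_labels: tuple[str, ...] = field(default_factory=tuple)


def efficiency_metrics(g: BinaryGraph) -> EfficiencyResult:
    """Compute every efficiency metric for one graph."""
    e_loc, nodal_loc = local_efficiency(g)
    return EfficiencyResult(
        global_efficiency=global_efficiency(g),
        local_efficiency=e_loc,
        nodal_local_efficiency=nodal_loc,
        nodal_global_efficiency=nodal_global_efficiency(g),
        subject=g.subject,
        session=g.session,
        roi_labels=g.roi_labels,
    )
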