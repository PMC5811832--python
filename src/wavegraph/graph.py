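"""Density thresholding: weighted connectivity -> binary graph.

Fixing the edge *density* (fraction of the R(R-1)/2 possible edges kept)
rather than a correlation cutoff guarantees every subject's graph has the
identical edge count, so between-subject differences in efficiency metrics
cannot be driven by differences in edge number.
"""

from __future__ import annotations

import numpy as np

from .types import BinaryGraph, ConnectivityMatrix, EdgeSet


def binarize_density(
    matrix: ConnectivityMatrix,
    density: float,
    rank_on: str = "absolute",
) -> BinaryGraph:
    """Keep the K strongest edges, K = floor(density * R(R-1)/2).

    rank_on : "absolute" ranks edges by |r| (default), "signed" by r.
    Ties are broken deterministically in ascending (i, j) lexicographic
    order, so repeated calls give the identical edge set.

    At the study's operating point (R = 90, density = 0.05) K = 200.
    """
    if not 0.0 < density < 1.0:
        raise ValueError("density must lie strictly between 0 and 1")
    if rank_on not in ("absolute", "signed"):
        raise ValueError("rank_on must be 'absolute' or 'signed'")

    r = matrix.n_rois
    n_possible = r * (r - 1) // 2
    k = int(np.floor(density * n_possible))
    if k == 0:
        raise ValueError(
            f"density {density} keeps 0 of {n_possible} edges — degenerate graph"
        )

    iu, ju = np.triu_indices(r, 1)
    w = matrix.values[iu, ju]
    key = np.abs(w) if rank_on == "absolute" else w
    # lexsort: last key is primary. Sort by (-key, i, j) ascending.
    order = np.lexsort((ju, iu, -key))
    keep = order[:k]

    adj = np.zeros((r, r), dtype=np.int8)
    adj[iu[keep], ju[keep]] = 1
    adj += adj.T
    edges = sorted(zip(iu[keep].tolist(), ju[keep].tolist()))
    return BinaryGraph(
        adjacency=adj,
        density=density,
        roi_labels=matrix.roi_labels,
        subject=matrix.subject,
        session=matrix.session,
        edge_list=EdgeSet(edges),
    )
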