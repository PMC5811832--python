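"""Independent brute-force oracles used to verify the implementation.

Everything here is deliberately naive — explicit loops, Floyd-Warshall,
exhaustive enumeration, projection matrices — and shares no code with the
package's own implementations.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats as sps


# ---------------------------------------------------------------- graphs


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if adj[i, j]:
                d[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def bf_global_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    d = floyd_warshall(adj)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def bf_nodal_global_efficiency(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = floyd_warshall(adj)
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                out[i] += 1.0 / d[i, j]
    return out / (n - 1)


def bf_local_efficiency(adj: np.ndarray) -> tuple[float, np.ndarray]:
    n = adj.shape[0]
    nodal = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        if len(nbrs) < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        nodal[i] = bf_global_efficiency(sub)
    return float(nodal.mean()), nodal


def random_graph(rng: np.random.Generator, n_max: int = 12) -> np.ndarray:
    n = int(rng.integers(2, n_max + 1))
    p = float(rng.uniform(0.05, 0.9))
    a = (rng.random((n, n)) < p).astype(int)
    a = np.triu(a, 1)
    return a + a.T


# ------------------------------------------------------------------- NBS


def bf_edge_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-column pooled two-sample t via scipy, groups as rows."""
    out = np.zeros(a.shape[1])
    for e in range(a.shape[1]):
        if a[:, e].var() == 0 and b[:, e].var() == 0:
            continue
        out[e] = sps.ttest_ind(a[:, e], b[:, e], equal_var=True).statistic
    return out


def bf_components(edge_idx: list[int], iu: np.ndarray, ju: np.ndarray):
    """Connected components (as edge-index sets) via networkx."""
    import networkx as nx

    g = nx.Graph()
    for e in edge_idx:
        g.add_edge(int(iu[e]), int(ju[e]), idx=e)
    comps = []
    for nodes in nx.connected_components(g):
        edges = [d["idx"] for _, _, d in g.subgraph(nodes).edges(data=True)]
        comps.append(sorted(edges))
    return comps


def bf_nbs_exhaustive(x: np.ndarray, n_a: int, threshold: float, sign: float = 1.0):
    """Exhaustive NBS over all label splits.

    x : (n, n_edges) pooled Fisher-z edge data; first n_a rows are the
    observed group A.  Returns (observed components as edge-index lists,
    their exact p-values, all max sizes).
    """
    n = x.shape[0]
    n_edges = x.shape[1]
    r = int((1 + np.sqrt(1 + 8 * n_edges)) / 2)
    iu, ju = np.triu_indices(r, 1)
    splits = list(combinations(range(n), n_a))

    def max_size(idx_a):
        mask = np.zeros(n, bool)
        mask[list(idx_a)] = True
        t = sign * bf_edge_t(x[mask], x[~mask])
        supra = [e for e in range(n_edges) if t[e] > threshold]
        comps = bf_components(supra, iu, ju)
        return max((len(c) for c in comps), default=0), comps

    obs_max, obs_comps = max_size(tuple(range(n_a)))
    all_max = [max_size(s)[0] for s in splits]
    pvals = {}
    for comp in obs_comps:
        pvals[tuple(comp)] = sum(m >= len(comp) for m in all_max) / len(splits)
    return obs_comps, pvals, all_max


# ------------------------------------------------------- split-plot ANOVA


def _proj_ss(y: np.ndarray, big: np.ndarray, small: np.ndarray) -> float:
    """||P_big y||^2 - ||P_small y||^2 via lstsq fits."""

    def fit(m):
        beta, *_ = np.linalg.lstsq(m, y, rcond=None)
        return m @ beta

    fb, fs = fit(big), fit(small)
    return float(fb @ fb - fs @ fs)


def bf_split_plot(y: np.ndarray, group_idx: np.ndarray):
    """Split-plot ANOVA via explicit projection matrices.

    y : (n_subjects, n_sessions); group_idx : integer group label per subject.
    Returns dict of (SS, df1, df2, F) per effect using sequential model
    comparisons: 1 < 1+G < Subj < Subj+Sess < Subj+G*Sess < full.
    """
    n, s = y.shape
    yy = y.reshape(-1)  # subject-major
    groups = np.unique(group_idx)
    g = len(groups)

    ones = np.ones((n * s, 1))
    G = np.zeros((n * s, g))
    Subj = np.zeros((n * s, n))
    Sess = np.zeros((n * s, s))
    GxS = np.zeros((n * s, g * s))
    for i in range(n):
        for k in range(s):
            row = i * s + k
            gi = int(np.nonzero(groups == group_idx[i])[0][0])
            G[row, gi] = 1
            Subj[row, i] = 1
            Sess[row, k] = 1
            GxS[row, gi * s + k] = 1

    ss_group = _proj_ss(yy, np.hstack([ones, G]), ones)
    ss_subj = _proj_ss(yy, Subj, np.hstack([ones, G]))
    ss_sess = _proj_ss(yy, np.hstack([Subj, Sess]), Subj)
    ss_inter = _proj_ss(yy, np.hstack([Subj, GxS]), np.hstack([Subj, Sess]))
    # ||y||^2 - ||P_[Subj,GxS] y||^2:
    beta, *_ = np.linalg.lstsq(np.hstack([Subj, GxS]), yy, rcond=None)
    fit_full = np.hstack([Subj, GxS]) @ beta
    ss_err = float(yy @ yy - fit_full @ fit_full)

    df = {
        "group": (g - 1, n - g),
        "drug": (s - 1, (n - g) * (s - 1)),
        "group:drug": ((g - 1) * (s - 1), (n - g) * (s - 1)),
    }
    out = {}
    for eff, ss_eff, ss_e, (d1, d2) in [
        ("group", ss_group, ss_subj, df["group"]),
        ("drug", ss_sess, ss_err, df["drug"]),
        ("group:drug", ss_inter, ss_err, df["group:drug"]),
    ]:
        f = (ss_eff / d1) / (ss_e / d2) if ss_e > 0 else np.nan
        out[eff] = {"SS": ss_eff, "df1": d1, "df2": d2, "F": f}
    out["_ss_subj"] = ss_subj
    out["_ss_err"] = ss_err
    return out


def bf_rm_anova(y: np.ndarray):
    """One-way RM ANOVA via projections (subject block + session)."""
    n, s = y.shape
    yy = y.reshape(-1)
    Subj = np.zeros((n * s, n))
    Sess = np.zeros((n * s, s))
    for i in range(n):
        for k in range(s):
            Subj[i * s + k, i] = 1
            Sess[i * s + k, k] = 1
    ss_sess = _proj_ss(yy, np.hstack([Subj, Sess]), Subj)
    beta, *_ = np.linalg.lstsq(np.hstack([Subj, Sess]), yy, rcond=None)
    fit = np.hstack([Subj, Sess]) @ beta
    ss_err = float(yy @ yy - fit @ fit)
    d1, d2 = s - 1, (n - 1) * (s - 1)
    return {"F": (ss_sess / d1) / (ss_err / d2), "df1": d1, "df2": d2}
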