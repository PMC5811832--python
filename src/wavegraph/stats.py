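"""Group-level inference on network metrics.

* split-plot (mixed) ANOVA — group as the between-subject factor, session
  (drug condition) as the within-subject factor, with the classical two
  error strata: subjects-within-groups for the between effect, and the
  session x subjects-within-groups residual for the within effects.
  Implemented directly from sums of squares so that a projection-matrix
  oracle can verify it exactly; with complete sessions the weighted main
  effects are orthogonal, so the sequential and weighted-means
  decompositions coincide even for unequal group sizes.
* one-way repeated-measures ANOVA — session effect within a single group,
  subject as blocking factor, with Greenhouse-Geisser epsilon reported
  for designs with more than two sessions.
* Pearson and partial Pearson correlations with two-sided t-based
  p-values (df = n - 2 - k after residualizing on k covariates).
* per-node group comparisons with Bonferroni correction over nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)


@dataclass
class CorrResult:
    R: float
    p: float
    n: int
    controlled_for: tuple[str, ...] = field(default_factory=tuple)


def _anova_row(
    effect: str, ss: float, df1: int, ss_err: float, df2: int, tol: float = 0.0
) -> dict:
    # ss below tol are rounding residue (e.g. all observations equal)
    ss = 0.0 if ss <= tol else ss
    ss_err = 0.0 if ss_err <= tol else ss_err
    ms = ss / df1
    ms_err = ss_err / df2
    f = 0.0 if ms == 0 else (np.inf if ms_err == 0 else ms / ms_err)
    p = 1.0 if ms == 0 else (0.0 if ms_err == 0 else float(sps.f.sf(f, df1, df2)))
    return {"effect": effect, "F": float(f), "df1": df1, "df2": df2, "p": p}


def _ss_tolerance(y: np.ndarray) -> float:
    scale = float(np.abs(y).max(initial=0.0))
    return (1e-10 * max(scale, 1e-300)) ** 2 * y.size


def _pivot_complete(
    metric: pd.DataFrame, sessions: tuple[str, ...], value: str = "value"
) -> pd.DataFrame:
    """Wide subject x session table restricted to subjects with every session."""
    sub = metric[metric["session"].isin(sessions)]
    wide = sub.pivot_table(index=["subject", "group"], columns="session", values=value)
    missing = [s for s in sessions if s not in wide.columns]
    if missing:
        raise ValueError(f"no data for session(s) {missing}")
    wide = wide[list(sessions)]
    n_before = len(wide)
    wide = wide.dropna()
    dropped = n_before - len(wide)
    if dropped:
        log.info("excluded %d subject(s) missing a session", dropped)
    return wide.reset_index()


def mixed_anova(
    metric: pd.DataFrame,
    sessions: tuple[str, ...] = ("placebo", "naltrexone"),
    value: str = "value",
) -> pd.DataFrame:
    """Split-plot ANOVA of a per-subject-session metric.

    metric : long table with columns subject, group, session, ``value``.
    Returns rows (group, drug, group:drug) with F, df1, df2, p.  Subjects
    missing any requested session are excluded (count logged).
    """
    wide = _pivot_complete(metric, tuple(sessions), value)
    groups = sorted(wide["group"].unique())
    if len(groups) < 2:
        raise ValueError("mixed ANOVA needs at least 2 groups")
    y = wide[list(sessions)].to_numpy(float)  # (N subjects, S sessions)
    g_idx = wide["group"].to_numpy()
    n_subj, s = y.shape
    n_g = np.array([(g_idx == g).sum() for g in groups])
    if np.any(n_g < 2):
        raise ValueError("every group needs at least 2 complete subjects")

    grand = y.mean()
    subj_means = y.mean(axis=1)
    sess_means = y.mean(axis=0)
    group_means = np.array([y[g_idx == g].mean() for g in groups])
    cell_means = np.array([y[g_idx == g].mean(axis=0) for g in groups])  # (g, s)

    ss_group = s * float(np.sum(n_g * (group_means - grand) ** 2))
    ss_subj = s * float(
        sum(
            ((subj_means[g_idx == g] - group_means[k]) ** 2).sum()
            for k, g in enumerate(groups)
        )
    )
    ss_session = n_subj * float(((sess_means - grand) ** 2).sum())
    inter = cell_means - group_means[:, None] - sess_means[None, :] + grand
    ss_inter = float(np.sum(n_g[:, None] * inter**2))
    fitted_cells = np.vstack([cell_means[groups.index(g)] for g in g_idx])
    resid = y - fitted_cells - (subj_means - np.array([group_means[groups.index(g)] for g in g_idx]))[:, None]
    ss_err_within = float((resid**2).sum())

    df_group = len(groups) - 1
    df_subj = n_subj - len(groups)
    df_session = s - 1
    df_inter = df_group * df_session
    df_err = df_subj * df_session

    tol = _ss_tolerance(y)
    rows = [
        _anova_row("group", ss_group, df_group, ss_subj, df_subj, tol),
        _anova_row("drug", ss_session, df_session, ss_err_within, df_err, tol),
        _anova_row("group:drug", ss_inter, df_inter, ss_err_within, df_err, tol),
    ]
    return pd.DataFrame(rows)


def one_way_rm_anova(
    metric: pd.DataFrame,
    sessions: tuple[str, ...] = ("baseline", "placebo", "naltrexone"),
    value: str = "value",
) -> pd.DataFrame:
    """One-way repeated-measures ANOVA (session effect, subject as block).

    For more than two sessions the table carries Greenhouse-Geisser
    epsilon and the epsilon-corrected p alongside the uncorrected one.
    """
    wide = _pivot_complete(metric, tuple(sessions), value)
    y = wide[list(sessions)].to_numpy(float)
    n, s = y.shape
    if n < 2 or s < 2:
        raise ValueError("need >= 2 subjects and >= 2 sessions")
    grand = y.mean()
    ss_session = n * float(((y.mean(axis=0) - grand) ** 2).sum())
    ss_subj = s * float(((y.mean(axis=1) - grand) ** 2).sum())
    ss_total = float(((y - grand) ** 2).sum())
    ss_err = ss_total - ss_session - ss_subj
    df1, df2 = s - 1, (n - 1) * (s - 1)
    row = _anova_row("session", ss_session, df1, ss_err, df2, _ss_tolerance(y))

    eps = 1.0
    if s > 2:
        sigma = np.cov(y, rowvar=False, ddof=1)
        centered = sigma - sigma.mean(axis=0) - sigma.mean(axis=1)[:, None] + sigma.mean()
        num = np.trace(centered) ** 2
        den = (s - 1) * float((centered**2).sum())
        eps = float(num / den) if den > 0 else 1.0
        eps = min(1.0, max(eps, 1.0 / (s - 1)))
    row["gg_epsilon"] = eps
    row["p_gg"] = float(sps.f.sf(row["F"], df1 * eps, df2 * eps)) if np.isfinite(row["F"]) else row["p"]
    return pd.DataFrame([row])


def pearson(x: np.ndarray, y: np.ndarray) -> CorrResult:
    """Pearson R with two-sided t-based p (df = n - 2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 4:
        raise ValueError("need n >= 4")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    r, p = sps.pearsonr(x, y)
    return CorrResult(R=float(r), p=float(p), n=len(x))


def partial_pearson(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None,
    names: tuple[str, ...] = (),
) -> CorrResult:
    """Pearson correlation of x and y after residualizing both on
    [intercept | covariates]; df = n - 2 - k."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if covariates is None or np.size(covariates) == 0:
        res = pearson(x, y)
        return CorrResult(R=res.R, p=res.p, n=res.n, controlled_for=tuple(names))
    z = np.asarray(covariates, float)
    if z.ndim == 1:
        z = z[:, None]
    n, k = z.shape
    if x.shape != (n,) or y.shape != (n,):
        raise ValueError("x, y, covariates must share the sample dimension")
    if n < 4 + k:
        raise ValueError(f"need n >= {4 + k} with {k} covariate(s)")
    design = np.column_stack([np.ones(n), z])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("zero residual variance")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    t = r * np.sqrt(df / (1.0 - r * r)) if abs(r) < 1 else np.inf
    p = float(2 * sps.t.sf(abs(t), df))
    return CorrResult(R=r, p=p, n=n, controlled_for=tuple(names))


def nodal_group_comparison(
    nodal: pd.DataFrame,
    groups: tuple[str, str],
    n_comparisons: int | None = None,
) -> pd.DataFrame:
    """Per-node two-sample t-tests with Bonferroni correction over nodes.

    nodal : long table with columns subject, group, roi, value (one session).
    Returns per-roi t, raw p, and p_bonferroni = min(1, p * n_nodes).
    """
    sub = nodal[nodal["group"].isin(groups)]
    rois = sorted(sub["roi"].unique())
    m = n_comparisons if n_comparisons is not None else len(rois)
    rows = []
    for roi in rois:
        a = sub[(sub["roi"] == roi) & (sub["group"] == groups[0])]["value"].to_numpy()
        b = sub[(sub["roi"] == roi) & (sub["group"] == groups[1])]["value"].to_numpy()
        t, p = sps.ttest_ind(a, b, equal_var=True)
        if not np.isfinite(t):  # zero variance in both samples
            t, p = 0.0, 1.0
        rows.append(
            {
                "roi": roi,
                "t": float(t),
                "p": float(p),
                "p_bonferroni": min(1.0, float(p) * m),
            }
        )
    return pd.DataFrame(rows)
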