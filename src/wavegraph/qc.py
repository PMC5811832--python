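"""Time-series-level quality control and confound removal.

DVARS — the root-mean-square across regions of the timepoint-to-timepoint
signal derivative — flags residual motion contamination: a volume whose
signal jumps by more than ``dvars_threshold`` standard-deviation units
relative to its predecessor marks the series as insufficiently
motion-corrected.  Subject removal under a stringent analysis is done as
an explicit design-table filter on the flags, never by silent deletion,
so exclusion counts stay auditable.

Confound removal is ordinary least squares: each ROI column is replaced
by its residual against [intercept | confounds], leaving residuals
exactly orthogonal to every confound regressor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import RoiTimeSeries


@dataclass(frozen=True)
class QcConfig:
    """dvars_threshold is in SD units (DVARS is computed on standardized
    series by default, so the published 'change > 2' rule keeps its
    meaning)."""

    dvars_threshold: float = 2.0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.dvars_threshold <= 0:
            raise ValueError("dvars_threshold must be positive")


@dataclass
class QcReport:
    subject: str
    session: str
    max_dvars: float
    flagged: bool
    n_flagged_timepoints: int
    dvars: np.ndarray  # length n_timepoints - 1


def compute_dvars(series: RoiTimeSeries, config: QcConfig = QcConfig()) -> QcReport:
    """DVARS_t = RMS across ROIs of (x_{i,t} - x_{i,t-1}), t >= 2.

    With ``standardize`` on, each ROI column is scaled to unit variance
    first; zero-variance columns are left alone (with a warning) and
    excluded from the RMS.  For standardized independent noise the
    expected DVARS is sqrt(2) per timepoint.
    """
    x = series.values
    if config.standardize:
        sd = x.std(axis=0, ddof=0)
        # relative tolerance: a column of identical values can carry an
        # O(eps) spurious standard deviation from the mean's rounding
        keep = sd > 1e-12 * np.abs(x).max(axis=0).clip(min=1e-300)
        if not keep.all():
            bad = [series.roi_labels[i] for i in np.nonzero(~keep)[0]]
            warnings.warn(
                f"constant ROI columns excluded from DVARS: {bad}",
                RuntimeWarning,
                stacklevel=2,
            )
        x = x[:, keep] / sd[keep]
        if x.shape[1] == 0:  # every column constant: no change by definition
            dvars = np.zeros(series.n_timepoints - 1)
            return QcReport(series.subject, series.session, 0.0, False, 0, dvars)
    diffs = np.diff(x, axis=0)
    dvars = np.sqrt((diffs**2).mean(axis=1))
    flagged_t = int((dvars > config.dvars_threshold).sum())
    return QcReport(
        subject=series.subject,
        session=series.session,
        max_dvars=float(dvars.max()),
        flagged=flagged_t > 0,
        n_flagged_timepoints=flagged_t,
        dvars=dvars,
    )


def qc_table(reports: list[QcReport]) -> pd.DataFrame:
    """Long-format QC report, one row per subject-session."""
    return pd.DataFrame(
        {
            "subject": [r.subject for r in reports],
            "session": [r.session for r in reports],
            "max_dvars": [r.max_dvars for r in reports],
            "n_flagged_timepoints": [r.n_flagged_timepoints for r in reports],
            "flagged": [r.flagged for r in reports],
        }
    )


def flag_subjects(reports: list[QcReport]) -> set[str]:
    """Subjects flagged in *any* session.

    The stringent analysis removes a flagged subject across all sessions
    (within-subject completeness is required by the repeated-measures
    design), so a single bad session excludes the subject.
    """
    return {r.subject for r in reports if r.flagged}


def regress_confounds(series: RoiTimeSeries, confounds: np.ndarray | None) -> RoiTimeSeries:
    """Replace each ROI column by its OLS residual against [1 | confounds].

    An empty confound set mean-centers each column.  Linearly dependent
    confound columns are dropped with a warning.  Residuals are exactly
    orthogonal to every retained confound column; the operation is
    idempotent.
    """
    x = series.values
    t = x.shape[0]
    if confounds is None or (hasattr(confounds, "size") and confounds.size == 0):
        design = np.ones((t, 1))
    else:
        c = np.asarray(confounds, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        if c.shape[0] != t:
            raise ValueError(
                f"confounds have {c.shape[0]} rows but series has {t} timepoints"
            )
        design = np.column_stack([np.ones(t), c])
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            # greedy drop of dependent columns (intercept always kept)
            kept = [0]
            for j in range(1, design.shape[1]):
                cand = design[:, kept + [j]]
                if np.linalg.matrix_rank(cand) > len(kept):
                    kept.append(j)
            warnings.warn(
                f"dropped {design.shape[1] - len(kept)} linearly dependent confound column(s)",
                RuntimeWarning,
                stacklevel=2,
            )
            design = design[:, kept]
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    resid = x - design @ beta
    return RoiTimeSeries(
        values=resid,
        tr=series.tr,
        roi_labels=series.roi_labels,
        subject=series.subject,
        session=series.session,
    )
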