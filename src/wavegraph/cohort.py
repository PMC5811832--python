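"""Synthetic multi-group, multi-session resting-state ROI cohorts.

No ROI time series were available for the study design this package
analyses (three groups — healthy volunteers, abstinent poly-substance
dependent, alcohol dependent — each scanned at baseline and under placebo
and naltrexone), so this module generates seeded cohorts with the same
structure and with *known* ground truth:

* modular covariance — ROIs are partitioned into modules sharing a
  band-limited latent factor, and the within-module coupling per
  group x session controls local network segregation (hence local
  efficiency).  Defaults plant the study's phenomenon: both patient
  groups more strongly coupled than controls, with the alcohol group
  alone dropping to control level under naltrexone.
* a planted edge subnetwork — a connected set of cross-module edges with
  extra pairwise coupling in some groups, so that reduced connectivity of
  a dispersed subnetwork in one group is recoverable by the
  network-based statistic.
* motion spikes — single-timepoint offsets of stated amplitude on all
  ROIs, producing controllable DVARS exceedances for QC tests.

Signal model for ROI i of module m (all latent terms unit variance):

    x_i = sqrt(rho) f_m + sum_e sqrt(delta_e) g_e + sqrt(1 - rho - sum delta_e) eps_i

with f_m band-limited module factors (FFT-masked white noise in the
carrier band), g_e per-planted-edge factors, eps_i white noise.  The
population correlation of two same-module ROIs is exactly rho, and a
planted edge adds exactly delta on top of any shared-module coupling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from typing import Mapping

import numpy as np
import pandas as pd

from .types import EdgeSet, RoiTimeSeries, default_roi_labels

GROUPS_DEFAULT = (("HV", 36), ("polySD", 36), ("AD", 21))
SESSIONS_DEFAULT = ("baseline", "placebo", "naltrexone")


def _default_coupling() -> dict[tuple[str, str], float]:
    # Operating point chosen where the 5%-density graph is sensitive to
    # modular coupling (at uniformly strong coupling the top-K edge set
    # saturates on same-module pairs and local efficiency stops
    # discriminating groups) and where the planted drug and group x drug
    # effects are reliably detectable at the default cohort size.
    c: dict[tuple[str, str], float] = {}
    for s in SESSIONS_DEFAULT:
        c[("HV", s)] = 0.12
        c[("polySD", s)] = 0.45
        c[("AD", s)] = 0.45
    c[("AD", "naltrexone")] = 0.12  # naltrexone normalises coupling in AD only
    return c


def _default_planted_edges() -> EdgeSet:
    # A connected, dispersed 20-edge subnetwork: a path alternating between
    # two modules (0,45,1,46,...,10), max degree 2 so the per-ROI shared
    # variance stays well below 1.
    nodes = []
    for k in range(11):
        nodes.append(k)
        if k < 10:
            nodes.append(45 + k)
    return EdgeSet(zip(nodes[:-1], nodes[1:]))


@dataclass(frozen=True)
class PlantedSubnetwork:
    """Edges carrying extra pairwise coupling, with a per-group delta."""

    edges: EdgeSet
    deltas: Mapping[str, float]

    def delta(self, group: str) -> float:
        return float(self.deltas.get(group, 0.0))


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort; identical spec+seed gives
    bit-identical output."""

    n_rois: int = 90
    n_timepoints: int = 180
    tr: float = 2.0
    groups: tuple[tuple[str, int], ...] = GROUPS_DEFAULT
    sessions: tuple[str, ...] = SESSIONS_DEFAULT
    n_modules: int = 6
    within_module_coupling: Mapping[tuple[str, str], float] | float = field(
        default_factory=_default_coupling
    )
    planted_subnetwork: PlantedSubnetwork | None = field(
        default_factory=lambda: PlantedSubnetwork(
            _default_planted_edges(),
            # reduced connectivity of the subnetwork in the alcohol group
            {"HV": 0.15, "polySD": 0.15, "AD": 0.0},
        )
    )
    carrier_band: tuple[float, float] = (0.0625, 0.125)
    noise_sd: float = 1.0
    spike_subjects: tuple[tuple[str, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois < 2 or self.n_timepoints < 4:
            raise ValueError("need at least 2 ROIs and 4 timepoints")
        for label, n in self.groups:
            if n < 2:
                raise ValueError(f"group {label!r} needs >= 2 subjects")
        if not 1 <= self.n_modules <= self.n_rois:
            raise ValueError("n_modules must lie in [1, n_rois]")
        f_lo, f_hi = self.carrier_band
        nyquist = 1.0 / (2.0 * self.tr)
        if not 0.0 < f_lo < f_hi <= nyquist:
            raise ValueError(
                f"carrier band {self.carrier_band} must lie inside (0, {nyquist}] Hz"
            )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for (g, s), rho in self._coupling_items():
            if not 0.0 <= rho < 1.0:
                raise ValueError(f"coupling for {(g, s)} must lie in [0, 1), got {rho}")
        if self.planted_subnetwork is not None:
            if self.planted_subnetwork.edges.max_index() >= self.n_rois:
                raise ValueError("planted edge references ROI index out of range")

    def _coupling_items(self):
        if isinstance(self.within_module_coupling, (int, float)):
            return [
                ((g, s), float(self.within_module_coupling))
                for g, _ in self.groups
                for s in self.sessions
            ]
        return list(self.within_module_coupling.items())

    def coupling(self, group: str, session: str) -> float:
        if isinstance(self.within_module_coupling, (int, float)):
            return float(self.within_module_coupling)
        return float(self.within_module_coupling.get((group, session), 0.0))

    def module_of(self, roi: int) -> int:
        """Contiguous near-equal-size module blocks."""
        return roi * self.n_modules // self.n_rois

    def subjects(self) -> list[tuple[str, str]]:
        """(subject_id, group) in deterministic generation order."""
        out = []
        for label, n in self.groups:
            out += [(f"sub-{label}{i + 1:03d}", label) for i in range(n)]
        return out


def with_coupling(spec: CohortSpec, coupling) -> CohortSpec:
    """Convenience: copy of spec with a new coupling map (or scalar)."""
    return replace(spec, within_module_coupling=coupling)


def band_limited_noise(
    rng: np.random.Generator, n: int, tr: float, band: tuple[float, float], size: int = 1
) -> np.ndarray:
    """(n, size) columns of unit-variance noise FFT-masked to a frequency band."""
    z = rng.standard_normal((n, size))
    spec = np.fft.rfft(z, axis=0)
    f = np.fft.rfftfreq(n, d=tr)
    mask = (f >= band[0]) & (f <= band[1])
    if not mask.any():
        raise ValueError(f"band {band} contains no DFT frequencies at n={n}, tr={tr}")
    spec[~mask] = 0.0
    x = np.fft.irfft(spec, n=n, axis=0)
    sd = x.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("degenerate band-limited factor (zero variance)")
    return x / sd


def _shared_variance(spec: CohortSpec, group: str, session: str) -> np.ndarray:
    """Per-ROI total latent-factor variance; must stay < 1."""
    rho = spec.coupling(group, session)
    shared = np.full(spec.n_rois, rho)
    if spec.planted_subnetwork is not None:
        d = spec.planted_subnetwork.delta(group)
        for i, j in spec.planted_subnetwork.edges:
            shared[i] += d
            shared[j] += d
    return shared


def generate_cohort(
    spec: CohortSpec,
) -> tuple[dict[tuple[str, str], RoiTimeSeries], pd.DataFrame]:
    """Generate every subject-session series plus the design table.

    Raises ValueError with a per-ROI diagnostic if the requested couplings
    imply a non-positive-definite target covariance (total shared variance
    >= 1 at some ROI).
    """
    for g, _ in spec.groups:
        for s in spec.sessions:
            shared = _shared_variance(spec, g, s)
            if np.any(shared >= 1.0):
                worst = int(np.argmax(shared))
                raise ValueError(
                    f"coupling combination for group={g!r}, session={s!r} gives "
                    f"total shared variance {shared[worst]:.3f} >= 1 at ROI {worst}: "
                    "target covariance not positive definite"
                )

    labels = default_roi_labels(spec.n_rois)
    modules = np.array([spec.module_of(i) for i in range(spec.n_rois)])
    spikes = dict(spec.spike_subjects)
    subjects = spec.subjects()

    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(len(subjects) * len(spec.sessions))

    series: dict[tuple[str, str], RoiTimeSeries] = {}
    rows = []
    k = 0
    for subj, group in subjects:
        for session in spec.sessions:
            rng = np.random.default_rng(children[k])
            k += 1
            x = _generate_series(spec, group, session, modules, rng)
            if subj in spikes:
                t_spike = int(rng.integers(1, spec.n_timepoints - 1))
                x[t_spike] += spikes[subj] * spec.noise_sd
            series[(subj, session)] = RoiTimeSeries(
                values=x, tr=spec.tr, roi_labels=labels, subject=subj, session=session
            )
            rows.append({"subject": subj, "group": group, "session": session})
    design = pd.DataFrame(rows)
    return series, design


def _generate_series(
    spec: CohortSpec,
    group: str,
    session: str,
    modules: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    t, r = spec.n_timepoints, spec.n_rois
    rho = spec.coupling(group, session)
    shared = _shared_variance(spec, group, session)

    factors = band_limited_noise(rng, t, spec.tr, spec.carrier_band, spec.n_modules)
    x = np.sqrt(rho) * factors[:, modules]
    if spec.planted_subnetwork is not None:
        d = spec.planted_subnetwork.delta(group)
        pair = band_limited_noise(
            rng, t, spec.tr, spec.carrier_band, len(spec.planted_subnetwork.edges)
        )
        if d > 0:
            for e, (i, j) in enumerate(spec.planted_subnetwork.edges):
                x[:, i] += np.sqrt(d) * pair[:, e]
                x[:, j] += np.sqrt(d) * pair[:, e]
    x += np.sqrt(1.0 - shared) * rng.standard_normal((t, r))
    return x * spec.noise_sd


# --------------------------------------------------------------------------
# covariates


_AGE = {"HV": (35.0, 8.0), "polySD": (38.0, 8.0), "AD": (42.0, 9.0)}
# exposure = years of regular use; HV and AD have no opiate history.
_EXPOSURE = {
    # group -> (alcohol mean/sd, cocaine mean/sd, opiate mean/sd)
    "HV": ((1.5, 1.0), (0.3, 0.5), (0.0, 0.0)),
    "polySD": ((12.0, 6.0), (8.0, 4.0), (6.0, 4.0)),
    "AD": ((18.0, 6.0), (2.0, 2.0), (0.0, 0.0)),
}


def generate_covariates(
    design: pd.DataFrame,
    seed: int,
    inject: tuple[str, np.ndarray, float] | None = None,
) -> pd.DataFrame:
    """Add per-subject age and substance-exposure columns to a design table.

    Exposure supports are group-appropriate: controls essentially unexposed,
    poly-substance users exposed to all three substances, the alcohol group
    heavily alcohol-exposed but opiate-naive (as are controls).

    inject : optional (column, metric, r) — ``metric`` is one value per
    subject (in design order); the named exposure column is regenerated as a
    mixture achieving population correlation ``r`` with the metric, for
    correlation-recovery tests.  ``r = 0`` injects pure noise.
    """
    subj = design.drop_duplicates("subject")[["subject", "group"]].reset_index(drop=True)
    rng = np.random.default_rng(seed)
    n = len(subj)

    cols: dict[str, np.ndarray] = {}
    age = np.empty(n)
    expo = {"alcohol_exposure": np.empty(n), "cocaine_exposure": np.empty(n), "opiate_exposure": np.empty(n)}
    for idx, grp in enumerate(subj["group"]):
        mu, sd = _AGE.get(grp, (38.0, 8.0))
        age[idx] = np.clip(rng.normal(mu, sd), 21.0, 64.0)
        for name, (m, s) in zip(expo, _EXPOSURE.get(grp, _EXPOSURE["HV"])):
            expo[name][idx] = 0.0 if s == 0 else max(0.0, rng.normal(m, s))
    cols["age"] = np.round(age, 1)
    for name, v in expo.items():
        cols[name] = np.round(v, 2)

    if inject is not None:
        column, metric, r = inject
        metric = np.asarray(metric, dtype=float)
        if metric.shape != (n,):
            raise ValueError(f"metric must have one value per subject ({n})")
        if not -1.0 < r < 1.0:
            raise ValueError("target correlation must lie in (-1, 1)")
        m_sd = metric.std(ddof=0)
        if m_sd == 0:
            raise ValueError("metric has zero variance")
        z = (metric - metric.mean()) / m_sd
        latent = r * z + np.sqrt(1.0 - r * r) * rng.standard_normal(n)
        base = cols.get(column)
        if base is None:
            raise ValueError(f"unknown exposure column {column!r}")
        scale = base.std(ddof=0) or 1.0
        cols[column] = np.round(base.mean() + scale * latent, 3)

    subj = subj.assign(**cols)
    base_design = design.drop(
        columns=[c for c in cols if c in design.columns], errors="ignore"
    )
    out = base_design.merge(subj.drop(columns="group"), on="subject", how="left")
    if (out.loc[out["group"].isin(["HV", "AD"]), "opiate_exposure"].fillna(0) != 0).any() and inject is None:
        warnings.warn("opiate exposure should be 0 for HV and AD", RuntimeWarning)
    return out
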