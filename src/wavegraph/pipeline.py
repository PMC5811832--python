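"""End-to-end orchestration: simulate -> QC -> connectivity -> metrics ->
{NBS, ANOVA, correlations}, with a provenance manifest.

Every stage logs the subject counts it keeps and drops, mirroring the
exclusion accounting a study report would carry.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .cohort import CohortSpec, generate_cohort, generate_covariates
from .efficiency import efficiency_metrics
from .graph import binarize_density
from .nbs import NbsConfig, component_report, nbs_test
from .qc import QcConfig, compute_dvars, flag_subjects, qc_table
from .stats import mixed_anova, one_way_rm_anova, partial_pearson, pearson
from .types import RoiTimeSeries
from .wavelet import WaveletSpec, wavelet_correlation_matrix

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything needed for a full deterministic run; round-trips through
    YAML losslessly."""

    seed: int = 0
    density: float = 0.05
    wavelet: WaveletSpec = field(default_factory=WaveletSpec)
    qc: QcConfig = field(default_factory=QcConfig)
    nbs: NbsConfig = field(default_factory=NbsConfig)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    nbs_session: str = "placebo"
    anova_sessions: tuple[str, str] = ("placebo", "naltrexone")
    apply_qc_filter: bool = False
    contrasts: tuple[tuple[str, str], ...] = (("AD", "HV"), ("polySD", "HV"), ("AD", "polySD"))

    def _payload(self) -> dict:
        payload = asdict(self)
        payload["cohort"]["within_module_coupling"] = {
            f"{g}|{s}": v for (g, s), v in self.cohort._coupling_items()
        }
        planted = self.cohort.planted_subnetwork
        payload["cohort"]["planted_subnetwork"] = (
            None
            if planted is None
            else {"edges": [list(e) for e in planted.edges], "deltas": dict(planted.deltas)}
        )
        return payload

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self._payload(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        from .cohort import PlantedSubnetwork
        from .types import EdgeSet

        payload = yaml.safe_load(Path(path).read_text())
        cohort = payload.pop("cohort", {})
        coupling = cohort.pop("within_module_coupling", 0.0)
        if isinstance(coupling, dict):
            coupling = {tuple(k.split("|")): v for k, v in coupling.items()}
        planted = cohort.pop("planted_subnetwork", None)
        if planted is not None:
            planted = PlantedSubnetwork(
                edges=EdgeSet(tuple(map(tuple, planted["edges"]))),
                deltas=planted["deltas"],
            )
        cohort = {
            k: (
                tuple(map(tuple, v))
                if k in ("groups", "spike_subjects")
                else tuple(v)
                if k in ("sessions", "carrier_band")
                else v
            )
            for k, v in cohort.items()
        }
        spec = CohortSpec(within_module_coupling=coupling, planted_subnetwork=planted, **cohort)
        return cls(
            seed=payload.get("seed", 0),
            density=payload.get("density", 0.05),
            wavelet=WaveletSpec(**payload.get("wavelet", {})),
            qc=QcConfig(**payload.get("qc", {})),
            nbs=NbsConfig(**payload.get("nbs", {})),
            cohort=spec,
            nbs_session=payload.get("nbs_session", "placebo"),
            anova_sessions=tuple(payload.get("anova_sessions", ("placebo", "naltrexone"))),
            apply_qc_filter=payload.get("apply_qc_filter", False),
            contrasts=tuple(map(tuple, payload.get("contrasts", ()))),
        )

    def config_hash(self) -> str:
        blob = json.dumps(self._payload(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def connectivity_for_cohort(
    series: dict[tuple[str, str], RoiTimeSeries], spec: WaveletSpec
) -> dict[tuple[str, str], "np.ndarray"]:
    return {key: wavelet_correlation_matrix(ts, spec) for key, ts in series.items()}


def metrics_table(matrices: dict, density: float) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Network-level and nodal long-format metric tables for all graphs."""
    net_rows, nodal_rows = [], []
    for (subj, sess), mat in matrices.items():
        g = binarize_density(mat, density)
        res = efficiency_metrics(g)
        net_rows += [
            {"subject": subj, "session": sess, "metric": "global_efficiency", "roi": "", "value": res.global_efficiency},
            {"subject": subj, "session": sess, "metric": "local_efficiency", "roi": "", "value": res.local_efficiency},
        ]
        for r, label in enumerate(res.roi_labels):
            nodal_rows += [
                {"subject": subj, "session": sess, "metric": "nodal_local_efficiency", "roi": label, "value": res.nodal_local_efficiency[r]},
                {"subject": subj, "session": sess, "metric": "nodal_global_efficiency", "roi": label, "value": res.nodal_global_efficiency[r]},
            ]
    return pd.DataFrame(net_rows), pd.DataFrame(nodal_rows)


def run_all(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline and write every documented artefact.

    Returns a summary dict (also written as summary.json).
    """
    out = Path(outdir)
    for sub in ("timeseries", "connectivity", "graphs", "stats"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    # 1. simulate
    series, design = generate_cohort(config.cohort)
    design = generate_covariates(design, seed=config.seed + 1)
    for (subj, sess), ts in series.items():
        io.write_timeseries(out / "timeseries" / f"{subj}_{sess}.tsv", ts)
    log.info("simulated %d subjects x %d sessions", design["subject"].nunique(), design["session"].nunique())

    # 2. QC
    reports = [compute_dvars(ts, config.qc) for ts in series.values()]
    qc_df = qc_table(reports)
    qc_df.to_csv(out / "qc_report.csv", index=False)
    flagged = flag_subjects(reports)
    design["qc_flagged"] = design["subject"].isin(flagged)
    io.write_design(out / "design.csv", design)
    log.info("QC flagged %d subject(s): %s", len(flagged), sorted(flagged))
    if config.apply_qc_filter and flagged:
        series = {k: v for k, v in series.items() if k[0] not in flagged}
        design = design[~design["subject"].isin(flagged)]
        log.info("stringent filter removed %d subject(s); %d remain", len(flagged), design["subject"].nunique())

    # 3. connectivity
    matrices = connectivity_for_cohort(series, config.wavelet)
    for (subj, sess), mat in matrices.items():
        io.write_matrix(out / "connectivity" / f"{subj}_{sess}.csv", mat)

    # 4. graphs + metrics
    net, nodal = metrics_table(matrices, config.density)
    io.write_metrics_long(out / "metrics_network.csv", net)
    io.write_metrics_long(out / "metrics_nodal.csv", nodal)

    # 5. NBS per contrast at the selected session
    summary: dict = {"config_hash": config.config_hash(), "seed": config.seed}
    groups_of = design.drop_duplicates("subject").set_index("subject")["group"]
    nbs_out = {}
    for ga, gb in config.contrasts:
        a = [matrices[(s, config.nbs_session)] for s in groups_of.index if groups_of[s] == ga and (s, config.nbs_session) in matrices]
        b = [matrices[(s, config.nbs_session)] for s in groups_of.index if groups_of[s] == gb and (s, config.nbs_session) in matrices]
        cfg = NbsConfig(
            t_threshold=config.nbs.t_threshold,
            n_permutations=config.nbs.n_permutations,
            direction="groupA_less",
            alpha=config.nbs.alpha,
            fisher_z=config.nbs.fisher_z,
            seed=config.seed + 101,
        )
        res = nbs_test(a, b, cfg)
        tag = f"{ga}_lt_{gb}_{config.nbs_session}"
        component_report(res).to_csv(out / "stats" / f"nbs_{tag}.csv", index=False)
        nbs_out[tag] = {
            "n_components": len(res.components),
            "largest_size": res.components[0].size if res.components else 0,
            "min_p_fwe": min((c.p_fwe for c in res.components), default=1.0),
        }
    summary["nbs"] = nbs_out

    # 6. ANOVA on network metrics
    anova_out = {}
    for metric_name in ("local_efficiency", "global_efficiency"):
        msub = net[net["metric"] == metric_name].merge(design[["subject", "group"]].drop_duplicates(), on="subject")
        tab = mixed_anova(msub, sessions=config.anova_sessions)
        tab.to_csv(out / "stats" / f"anova_{metric_name}.csv", index=False)
        anova_out[metric_name] = {
            row["effect"]: {"F": row["F"], "df1": int(row["df1"]), "df2": int(row["df2"]), "p": row["p"]}
            for _, row in tab.iterrows()
        }
        if len(config.cohort.sessions) >= 3:
            for grp in sorted({g for g, _ in config.cohort.groups}):
                sub = msub[msub["group"] == grp]
                rm = one_way_rm_anova(sub, sessions=tuple(config.cohort.sessions))
                rm.to_csv(out / "stats" / f"rm_anova_{metric_name}_{grp}.csv", index=False)
    summary["anova"] = anova_out

    # 7. correlations with exposure on the drug-control session
    placebo = net[(net["metric"] == "local_efficiency") & (net["session"] == config.nbs_session)]
    merged = placebo.merge(design[design["session"] == config.nbs_session], on=["subject", "session"])
    patients = merged[merged["group"].isin(["AD", "polySD"])]
    corr_rows = []
    for expo in ("opiate_exposure", "cocaine_exposure", "alcohol_exposure"):
        if patients[expo].std() == 0:
            continue
        res = pearson(patients["value"].to_numpy(), patients[expo].to_numpy())
        corr_rows.append({"x": "local_efficiency", "y": expo, "R": res.R, "p": res.p, "n": res.n, "controlled_for": ""})
        part = partial_pearson(
            patients["value"].to_numpy(),
            patients[expo].to_numpy(),
            patients["age"].to_numpy(),
            names=("age",),
        )
        corr_rows.append({"x": "local_efficiency", "y": expo, "R": part.R, "p": part.p, "n": part.n, "controlled_for": "age"})
    corr_df = pd.DataFrame(corr_rows)
    corr_df.to_csv(out / "stats" / "correlations.csv", index=False, float_format="%.10g")
    summary["correlations"] = corr_rows

    # provenance manifest
    manifest = {
        "package": "wavegraph",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_subjects": int(design["subject"].nunique()),
        "n_flagged": len(flagged),
    }
    io.write_json(out / "manifest.json", manifest)
    io.write_json(out / "summary.json", summary)
    config.to_yaml(out / "config.yaml")
    return summary
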