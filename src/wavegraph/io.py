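"""Plain-text readers/writers for every pipeline artefact.

Formats (all UTF-8, newline-terminated):

* time series — TSV, one row per timepoint, header row = ROI labels;
  sampling interval recorded in a sidecar/manifest.
* design table — CSV with subject, group, session and covariate columns.
* connectivity matrices — square CSV with ROI labels as header row and
  index column; scale and identifiers in a sidecar JSON.
* binary graphs — edge-list TSV (roi_i, roi_j) plus square 0/1 CSV.
* metrics — long-format CSV: subject, session, metric, roi (blank for
  network-level values), value.
* confounds — headerless TSV matrix, timepoints x k.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import BinaryGraph, ConnectivityMatrix, RoiTimeSeries

FLOAT_FMT = "%.10g"


def write_timeseries(path: str | Path, series: RoiTimeSeries) -> None:
    df = pd.DataFrame(series.values, columns=list(series.roi_labels))
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_timeseries(
    path: str | Path, tr: float, subject: str = "", session: str = ""
) -> RoiTimeSeries:
    df = pd.read_csv(path, sep="\t")
    return RoiTimeSeries(
        values=df.to_numpy(float),
        tr=tr,
        roi_labels=tuple(df.columns),
        subject=subject,
        session=session,
    )


def write_design(path: str | Path, design: pd.DataFrame) -> None:
    design.to_csv(path, index=False)


def read_design(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_matrix(path: str | Path, matrix: ConnectivityMatrix) -> None:
    labels = list(matrix.roi_labels)
    df = pd.DataFrame(matrix.values, index=labels, columns=labels)
    df.to_csv(path, float_format=FLOAT_FMT)
    sidecar = Path(path).with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "scale": matrix.scale,
                "subject": matrix.subject,
                "session": matrix.session,
                "n_rois": matrix.n_rois,
            },
            indent=2,
        )
        + "\n"
    )


def read_matrix(path: str | Path) -> ConnectivityMatrix:
    df = pd.read_csv(path, index_col=0)
    sidecar = Path(path).with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return ConnectivityMatrix(
        values=df.to_numpy(float),
        scale=int(meta.get("scale", 0)),
        roi_labels=tuple(df.columns),
        subject=meta.get("subject", ""),
        session=meta.get("session", ""),
    )


def write_graph(path_edges: str | Path, graph: BinaryGraph, path_adj: str | Path | None = None) -> None:
    with open(path_edges, "w") as fh:
        fh.write("roi_i\troi_j\n")
        for i, j in graph.edge_list:
            fh.write(f"{graph.roi_labels[i]}\t{graph.roi_labels[j]}\n")
    if path_adj is not None:
        labels = list(graph.roi_labels)
        pd.DataFrame(graph.adjacency, index=labels, columns=labels).to_csv(path_adj)


def read_confounds(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t", ndmin=2)


def write_confounds(path: str | Path, confounds: np.ndarray) -> None:
    np.savetxt(path, np.atleast_2d(confounds), delimiter="\t", fmt=FLOAT_FMT)


def write_metrics_long(path: str | Path, rows: pd.DataFrame) -> None:
    rows.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
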