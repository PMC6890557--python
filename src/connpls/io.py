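"""Readers and writers for the pipeline's plain-text interchange formats.

All tabular artifacts are TSV with a header row and a ``subject_id`` column;
floats are written with 17 significant digits so a write-read round trip is
exact.  Feature tables carry a JSON sidecar recording the ROI count, the
connectivity method and the edge order.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import EdgeIndexMap, FeatureMatrix
from .crossval import LabelTable

__all__ = ["read_feature_table", "write_feature_table", "read_label_table",
           "write_label_table", "read_timeseries_manifest", "write_results_json"]

_FLOAT_FMT = "%.17g"


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if "subject_id" not in df.columns:
        raise ValueError(f"{path}: missing required 'subject_id' column")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate subject ids {sorted(set(dup))}")
    return df.set_index("subject_id")


def write_feature_table(features: FeatureMatrix, path) -> None:
    path = Path(path)
    features.to_frame().to_csv(path, sep="\t", float_format=_FLOAT_FMT)
    sidecar = {"p": features.edge_map.p, "n_edges": features.edge_map.n_edges,
               "edge_order": "lexicographic upper triangle, 0-based (i<j)"}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_feature_table(path) -> FeatureMatrix:
    """Load a subjects x edges TSV/CSV; the edge count must be triangular."""
    df = _read_tsv(path)
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)].tolist()
        raise ValueError(f"{path}: missing feature values for subject(s) {bad}")
    n_edges = df.shape[1]
    round_p = int(round((1 + np.sqrt(1 + 8 * n_edges)) / 2))
    if round_p * (round_p - 1) // 2 != n_edges:
        raise ValueError(f"{path}: {n_edges} columns is not p(p-1)/2 for any p")
    return FeatureMatrix(values=df.to_numpy(float), edge_map=EdgeIndexMap(round_p),
                         subject_ids=df.index.astype(str).tolist())


def write_label_table(labels: LabelTable, path) -> None:
    path = Path(path)
    labels.to_frame().to_csv(path, sep="\t", float_format=_FLOAT_FMT)
    sidecar = {"kinds": dict(zip(labels.names, labels.kinds))}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_label_table(path, kinds=None, missing: str = "error") -> LabelTable:
    """Load a subjects x labels TSV/CSV.

    ``kinds`` maps label name to "continuous"/"binary"; unlisted labels are
    inferred (exactly-{0,1}-valued columns are binary).  ``missing`` is
    ``"error"`` (default: any incomplete subject is a hard failure, with the
    offenders named) or ``"drop"`` (subjects with any missing label are
    excluded, as incomplete participants are excluded from analysis).
    """
    path = Path(path)
    df = _read_tsv(path)
    incomplete = df.index[df.isna().any(axis=1)].tolist()
    if incomplete:
        if missing == "drop":
            df = df.dropna()
        else:
            raise ValueError(f"{path}: missing labels for subject(s) {incomplete}")
    if kinds is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            kinds = json.loads(sidecar.read_text()).get("kinds", {})
        else:
            kinds = {}
    kind_list = []
    for col in df.columns:
        if col in kinds:
            kind_list.append(kinds[col])
        else:
            vals = set(df[col].unique())
            kind_list.append("binary" if vals <= {0, 1, 0.0, 1.0} else "continuous")
    return LabelTable(values=df.to_numpy(float), names=list(df.columns),
                      kinds=kind_list, subject_ids=df.index.astype(str).tolist())


def read_timeseries_manifest(path):
    """Load a manifest TSV (subject_id, file, family_id) and the per-subject
    time-series TSVs it points to; returns (timeseries, subject_ids, family_id)."""
    path = Path(path)
    df = _read_tsv(path).reset_index()
    if "file" not in df.columns:
        raise ValueError(f"{path}: manifest needs a 'file' column")
    base = path.parent
    timeseries = [np.loadtxt(base / f, delimiter="\t", ndmin=2)
                  for f in df["file"]]
    family = (df["family_id"].to_numpy() if "family_id" in df.columns
              else np.arange(len(df)))
    return timeseries, df["subject_id"].astype(str).tolist(), family


def write_results_json(obj: dict, path) -> None:
    """JSON writer tolerant of numpy scalars/arrays."""
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=1, default=default))
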