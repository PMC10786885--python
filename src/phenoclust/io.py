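"""Readers and writers for the plain-text interchange formats.

Screen side: ``library.tsv`` (construct registry), ``counts.tsv``
(construct x sample integers), ``samples.csv`` (arm/timepoint/replicate),
``results.tsv``.  Methylation side: ``beta.tsv`` / ``detp.tsv`` (probe x
sample floats) and ``probes.tsv`` (chrom and filter flags).  All tables are
pandas DataFrames in memory.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .screen import validate_counts, validate_library, validate_samples


def _require_columns(df: pd.DataFrame, required, what: str, path) -> None:
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{what} {path} is missing columns: {sorted(missing)}")


def read_library(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"construct_id": str})
    _require_columns(
        df, ["construct_id", "gene", "protospacer_a", "protospacer_b", "is_ntc"],
        "library", path,
    )
    df = df.set_index("construct_id")
    df["is_ntc"] = df["is_ntc"].astype(int).astype(bool)
    validate_library(df)
    return df


def write_library(library: pd.DataFrame, path) -> None:
    out = library.copy()
    out["is_ntc"] = out["is_ntc"].astype(int)
    out.to_csv(path, sep="\t")


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="construct_id")
    if not all(np.issubdtype(t, np.integer) for t in df.dtypes):
        raise ValueError(f"counts {path} must contain integer columns only")
    validate_counts(df)
    return df


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="construct_id")


def read_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str})
    _require_columns(df, ["sample_id", "arm", "timepoint", "replicate"],
                     "sample sheet", path)
    df = df.set_index("sample_id")
    validate_samples(df)
    return df


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path)


def write_results(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index_label="construct_id")


def read_beta(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="probe_id")
    values = df.to_numpy()
    if ((values < 0) | (values > 1)).any():
        i, j = np.argwhere((values < 0) | (values > 1))[0]
        raise ValueError(
            f"beta {path}: value {values[i, j]!r} outside [0, 1] at probe "
            f"{df.index[i]}, sample {df.columns[j]}"
        )
    return df


def write_beta(beta: pd.DataFrame, path) -> None:
    beta.to_csv(path, sep="\t", index_label="probe_id", float_format="%.6g")


def read_detection_p(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="probe_id")
    values = df.to_numpy()
    if ((values < 0) | (values > 1)).any():
        raise ValueError(f"detection-p {path} contains values outside [0, 1]")
    return df


def read_probe_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="probe_id")
    _require_columns(df, ["chrom", "snp_overlap", "multimap"],
                     "probe annotation", path)
    df["snp_overlap"] = df["snp_overlap"].astype(int).astype(bool)
    df["multimap"] = df["multimap"].astype(int).astype(bool)
    return df


def write_probe_annotation(annotation: pd.DataFrame, path) -> None:
    out = annotation.copy()
    out["snp_overlap"] = out["snp_overlap"].astype(int)
    out["multimap"] = out["multimap"].astype(int)
    out.to_csv(path, sep="\t", index_label="probe_id")


def write_truth(truth, path) -> None:
    """Write the planted truth as a two-column (id, label) TSV."""
    parts = []
    if truth.construct_classes is not None:
        parts.append(truth.construct_classes.rename("label").rename_axis("id"))
    if truth.sample_groups is not None:
        parts.append(truth.sample_groups.rename("label").rename_axis("id"))
    if truth.probe_groups is not None:
        probe = truth.probe_groups.dropna().rename("label").rename_axis("id")
        parts.append(probe)
    pd.concat(parts).to_csv(path, sep="\t")


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return _to_jsonable(obj.tolist())
    if isinstance(obj, (pd.Series, pd.Index)):
        return _to_jsonable(obj.tolist())
    return obj


def write_summary(summary: dict, path) -> None:
    Path(path).write_text(json.dumps(_to_jsonable(summary), indent=2) + "\n")
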