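"""Plain-text readers and writers for the pipeline's tabular artifacts."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .synthetic import StudyDesign

__all__ = [
    "read_matrix", "write_matrix", "read_metadata", "write_metadata",
    "read_qpcr", "write_qpcr", "read_design", "write_design",
    "write_manifest",
]


def read_matrix(path) -> pd.DataFrame:
    """Probes x samples TSV (first column probe_id, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "probe_id"
    return df


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.rename_axis("probe_id").to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample")


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t")


def read_qpcr(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_qpcr(qpcr: pd.DataFrame, path) -> None:
    qpcr.to_csv(path, sep="\t", index=False)


def read_design(path) -> StudyDesign:
    raw = yaml.safe_load(Path(path).read_text())
    if raw.get("tod") is not None:
        raw["tod"] = tuple(raw["tod"])
    return StudyDesign(**raw)


def write_design(design: StudyDesign, path) -> None:
    data = {
        "n_neg": design.n_neg, "n_pos": design.n_pos,
        "n_cws": design.n_cws, "n_irh": design.n_irh,
        "n_probes": design.n_probes, "probes_per_gene": design.probes_per_gene,
        "tod": list(design.tod) if design.tod is not None else None,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
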