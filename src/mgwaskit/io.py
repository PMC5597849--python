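"""Plain-text (TSV/JSON) readers and writers for the pipeline tables.

All on-disk formats are uncompressed tab-separated text so that datasets
remain diffable and portable. Matrices are stored features-by-samples with
the feature id in the first column.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

CATALOG_COLUMNS = [
    "gene_id",
    "length_bp",
    "taxon_id",
    "genus",
    "phylum",
    "dna_identity",
    "protein_identity",
    "coverage",
    "ko_id",
    "module_id",
]

COHORT_COLUMNS = [
    "sample_id",
    "group",
    "glucose_0",
    "glucose_60",
    "glucose_120",
    "pbmi",
    "age",
]


def read_catalog(path: str | Path) -> pd.DataFrame:
    """Read a gene catalogue TSV, validating required columns."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"catalog at {path} is missing columns: {missing}")
    return df.set_index("gene_id", drop=False)


def write_catalog(catalog: pd.DataFrame, path: str | Path) -> None:
    catalog.loc[:, CATALOG_COLUMNS].to_csv(path, sep="\t", index=False)


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a features-by-samples matrix TSV (first column = feature id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(matrix: pd.DataFrame, path: str | Path, index_name: str = "feature_id") -> None:
    out = matrix.copy()
    out.index.name = out.index.name or index_name
    out.to_csv(path, sep="\t")


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort at {path} is missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        raise ValueError("cohort sample ids must be unique")
    return df.set_index("sample_id", drop=False)


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.loc[:, COHORT_COLUMNS].to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
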