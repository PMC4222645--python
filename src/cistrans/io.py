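"""Deterministic TSV input/output for pipeline tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

FLOAT_FORMAT = "%.10g"

COUNT_COLUMNS = [
    "gene_id",
    "tissue",
    "genotype",
    "replicate",
    "maize_count",
    "teosinte_count",
]


def write_tsv(df: pd.DataFrame, path) -> None:
    """Write a TSV with a header and fixed float formatting.

    Row order is the caller's responsibility (stages sort by gene and
    tissue), so identical inputs give byte-identical files.
    """
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)


def read_counts(path) -> pd.DataFrame:
    """Read and validate a replicate-level allele-count table."""
    df = read_tsv(path, dtype={"gene_id": str, "tissue": str, "genotype": str})
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"count table {path} is missing columns: {sorted(missing)}")
    for col in ("maize_count", "teosinte_count"):
        if (df[col] < 0).any():
            bad = df.index[df[col] < 0][:5].tolist()
            raise ValueError(f"negative {col} in {path} at rows {bad}")
    dup = df.duplicated(["gene_id", "tissue", "genotype", "replicate"])
    if dup.any():
        bad = df.index[dup][:5].tolist()
        raise ValueError(f"duplicate (gene,tissue,genotype,replicate) rows: {bad}")
    return df
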