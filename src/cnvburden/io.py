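"""Tabular input/output.

All interchange is header-carrying TSV. Genomic coordinates are 1-based
inclusive internally (the convention of the CNV-caller call files this
pipeline consumes); BED gene annotations are 0-based half-open on disk and
converted on read.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

CALL_COLUMNS = ["sample_id", "caller_id", "chromosome", "start_bp", "end_bp", "copy_number", "n_markers"]
MARKER_COLUMNS = ["marker_id", "chromosome", "position_bp", "is_cnv_probe"]


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chromosome": str})


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_marker_map(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path)
    missing = set(MARKER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"marker map missing columns: {sorted(missing)}")
    return df


def read_caller_calls(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path)
    missing = set(CALL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"call table missing columns: {sorted(missing)}")
    return df


def read_gene_bed(path: str | Path) -> pd.DataFrame:
    """Read a gene annotation BED (chrom, start, end, name).

    BED is 0-based half-open; returned coordinates are 1-based inclusive,
    i.e. start+1 and end unchanged.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2, 3],
        names=["chromosome", "start_bp", "end_bp", "gene_id"],
        dtype={"chromosome": str},
        comment="#",
    )
    df["start_bp"] = df["start_bp"].astype(int) + 1
    df["end_bp"] = df["end_bp"].astype(int)
    return df[["gene_id", "chromosome", "start_bp", "end_bp"]]


def write_gene_bed(genes: pd.DataFrame, path: str | Path) -> None:
    """Write genes (1-based inclusive) back to 0-based half-open BED."""
    out = pd.DataFrame(
        {
            "chromosome": genes["chromosome"],
            "start": genes["start_bp"].astype(int) - 1,
            "end": genes["end_bp"].astype(int),
            "name": genes["gene_id"],
        }
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", index=False, header=False, lineterminator="\n")
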