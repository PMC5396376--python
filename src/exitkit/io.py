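"""Readers and writers for the plain-text formats the pipeline exchanges.

Internally all coordinates are 0-based half-open. The bismark-coverage
dialect (1-based, inclusive) is converted at this boundary only.
"""

from __future__ import annotations

import os
from typing import Mapping

import pandas as pd
from pyfaidx import Faidx, Fasta

CPG_COLUMNS = ["chrom", "pos", "meth", "unmeth"]
BED_COLUMNS = ["chrom", "start", "end", "name"]


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike, width: int = 70) -> None:
    """Write sequences to FASTA and build a .fai index next to it."""
    path = os.fspath(path)
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    Faidx(path, rebuild=True)


def read_fasta(path: str | os.PathLike) -> Fasta:
    return Fasta(os.fspath(path), as_raw=True, sequence_always_upper=True)


def write_bismark_coverage(records: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write CpG records as bismark coverage: chrom, 1-based pos, pos, %, meth, unmeth."""
    cov = records["meth"] + records["unmeth"]
    out = pd.DataFrame(
        {
            "chrom": records["chrom"],
            "start": records["pos"] + 1,
            "end": records["pos"] + 1,
            "pct": 100.0 * records["meth"] / cov,
            "meth": records["meth"],
            "unmeth": records["unmeth"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def read_bismark_coverage(path: str | os.PathLike) -> pd.DataFrame:
    """Read bismark coverage into 0-based CpG records (chrom, pos, meth, unmeth)."""
    raw = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "pct", "meth", "unmeth"],
        dtype={"chrom": str},
    )
    return pd.DataFrame(
        {
            "chrom": raw["chrom"],
            "pos": raw["start"].astype(int) - 1,
            "meth": raw["meth"].astype(int),
            "unmeth": raw["unmeth"].astype(int),
        }
    )


def write_bed(intervals: pd.DataFrame, path: str | os.PathLike) -> None:
    cols = [c for c in BED_COLUMNS if c in intervals.columns]
    extra = [c for c in intervals.columns if c not in cols]
    intervals[cols + extra].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | os.PathLike, names: list[str] | None = None) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    names = names or BED_COLUMNS
    raw.columns = names[: raw.shape[1]] + [f"col{i}" for i in range(len(names), raw.shape[1])]
    raw["start"] = raw["start"].astype(int)
    raw["end"] = raw["end"].astype(int)
    return raw


def write_table(df: pd.DataFrame, path: str | os.PathLike, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path: str | os.PathLike, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_gene_table(genes: pd.DataFrame, path: str | os.PathLike) -> None:
    genes.to_csv(path, sep="\t", index=False)


def read_gene_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})
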