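"""Readers and writers for the pipeline's on-disk formats.

Counts travel as genes x samples TSV or as an MTX triple (MatrixMarket
matrix plus gene and sample name files); metadata, annotation, depth
profiles, and fit results as TSV; peaks as 6-column BED (0-based,
half-open); categories as GMT-style text. Every writer is paired with a
reader and round-trips losslessly on the in-memory data model.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "read_counts_tsv", "write_counts_tsv",
    "read_counts_mtx", "write_counts_mtx",
    "read_table", "write_table",
    "read_bed", "write_bed",
    "read_gmt", "write_gmt",
]

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_counts_tsv(counts: pd.DataFrame, path):
    counts.to_csv(path, sep="\t", index_label="gene")


def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene"
    df.columns.name = "sample"
    return df


def write_counts_mtx(counts: pd.DataFrame, prefix):
    """Write counts as <prefix>.mtx plus <prefix>.genes.txt / .samples.txt."""
    prefix = Path(prefix)
    spio.mmwrite(str(prefix.with_suffix(".mtx")), sparse.csr_matrix(counts.to_numpy()))
    prefix.with_suffix(".genes.txt").write_text("\n".join(map(str, counts.index)) + "\n")
    prefix.with_suffix(".samples.txt").write_text("\n".join(map(str, counts.columns)) + "\n")


def read_counts_mtx(prefix) -> pd.DataFrame:
    prefix = Path(prefix)
    m = spio.mmread(str(prefix.with_suffix(".mtx")))
    genes = prefix.with_suffix(".genes.txt").read_text().splitlines()
    samples = prefix.with_suffix(".samples.txt").read_text().splitlines()
    dense = np.asarray(m.todense() if sparse.issparse(m) else m)
    df = pd.DataFrame(dense.astype(np.int64), index=genes, columns=samples)
    df.index.name = "gene"
    df.columns.name = "sample"
    return df


def write_table(df: pd.DataFrame, path, index: bool = True):
    df.to_csv(path, sep="\t", index=index)


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_bed(peaks: pd.DataFrame, path):
    cols = [c for c in BED_COLUMNS if c in peaks.columns]
    peaks[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    """Parse a BED file (>= 3 columns), reporting malformed lines by number."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >= 3 tab-separated fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise ValueError(f"{path}: line {lineno}: invalid interval [{start}, {end})")
            row = {"chrom": parts[0], "start": start, "end": end}
            for i, col in enumerate(("name", "score", "strand"), start=3):
                if len(parts) > i:
                    row[col] = parts[i]
            rows.append(row)
    df = pd.DataFrame(rows)
    if "score" in df.columns:
        df["score"] = pd.to_numeric(df["score"], errors="coerce").fillna(0).astype(int)
    return df


def write_gmt(categories: dict, path):
    with open(path, "w") as fh:
        for name, genes in categories.items():
            fh.write("\t".join([name, name] + [str(g) for g in genes]) + "\n")


def read_gmt(path) -> dict:
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected name, description, genes")
            out[parts[0]] = set(parts[2:])
    return out
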