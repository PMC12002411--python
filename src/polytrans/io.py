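"""Readers and writers for the standard formats used across the pipeline.

Counts travel as MTX triplets (single cell) or dense TSV (bulk); sequences as
FASTA with region-suffixed IDs (``<tx>|5UTR`` etc.); gene sets as GMT. All
tables are written with a header row preceded by a ``#`` comment line carrying
the tool version and, when available, the configuration hash.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import io as spio
from scipy import sparse

from . import __version__

REGIONS = ("5UTR", "CDS", "3UTR")


def _comment_line(config_hash: str | None = None) -> str:
    tag = f"# polytrans v{__version__}"
    if config_hash:
        tag += f" config={config_hash}"
    return tag + "\n"


def write_table(df: pd.DataFrame, path, config_hash: str | None = None,
                index: bool = False) -> None:
    """Write a TSV with a version comment line above the header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_comment_line(config_hash))
        df.to_csv(fh, sep="\t", index=index)


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_mtx(counts: np.ndarray, cells: pd.DataFrame, genes: pd.Index,
              outdir) -> None:
    """Write a cell x gene matrix as matrix.mtx + cells.tsv + genes.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(outdir / "matrix.mtx"), sparse.coo_matrix(counts))
    cells.to_csv(outdir / "cells.tsv", sep="\t")
    pd.Series(genes, name="gene").to_csv(outdir / "genes.tsv", sep="\t",
                                         index=False)


def read_mtx(indir):
    """Read the triplet written by :func:`write_mtx`.

    Returns (counts ndarray, cells DataFrame, genes Index).
    """
    indir = Path(indir)
    counts = np.asarray(spio.mmread(str(indir / "matrix.mtx")).todense())
    cells = pd.read_csv(indir / "cells.tsv", sep="\t", index_col=0)
    genes = pd.Index(pd.read_csv(indir / "genes.tsv", sep="\t")["gene"])
    return counts.astype(np.int64), cells, genes


def write_fasta(seqs: dict[str, str], path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into {id: sequence}, uppercasing lowercase bases."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def split_regions(seqs: dict[str, str]) -> dict[str, dict[str, str]]:
    """Group region-suffixed records (``tx|5UTR``) by region label."""
    out: dict[str, dict[str, str]] = {r: {} for r in REGIONS}
    for name, seq in seqs.items():
        if "|" not in name:
            raise ValueError(f"record id {name!r} lacks a |REGION suffix")
        tx, region = name.rsplit("|", 1)
        if region not in out:
            raise ValueError(f"unknown region {region!r} in record {name!r}")
        out[region][tx] = seq
    return out


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection: name <tab> description <tab> members."""
    collection: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            collection[fields[0]] = {g for g in fields[2:] if g}
    return collection


def write_gmt(collection: dict[str, set[str]], path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, members in collection.items():
            fh.write("\t".join([name, "na"] + sorted(members)) + "\n")


def write_bed(intervals: pd.DataFrame, path) -> None:
    """Write BED3+ (0-based, half-open). Expects columns chrom/start/end first."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    intervals.to_csv(path, sep="\t", header=False, index=False)


def table_to_string(df: pd.DataFrame, index: bool = False) -> str:
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=index)
    return buf.getvalue()
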