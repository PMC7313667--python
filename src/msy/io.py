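"""Light wrappers for the plain-text formats the pipeline exchanges.

FASTA goes through Biopython; FASTQ reading uses Biopython's fast
general iterator.  FASTQ writing is done directly (the four-line record
layout), which is the approach Biopython's own documentation recommends
for large simple files.  Placed reads and tables travel as TSV/CSV via
pandas; the planted-truth interval as BED.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_placed_reads",
    "write_placed_reads",
    "read_bed",
    "write_bed",
]


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | os.PathLike) -> Iterator[tuple[str, str, str]]:
    """Yield ``(title, sequence, quality)`` tuples."""
    with open(path) as fh:
        yield from FastqGeneralIterator(fh)


def write_fastq(reads: Iterable[tuple[str, str, str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for title, seq, qual in reads:
            fh.write(f"@{title}\n{seq}\n+\n{qual}\n")


PLACED_COLUMNS = ["chrom", "start", "end"]


def read_placed_reads(path: str | os.PathLike) -> pd.DataFrame:
    """Read a placed-read TSV (chrom, start, end; 0-based half-open)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "start": int, "end": int})
    missing = [c for c in PLACED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"placed-read table lacks columns: {missing}")
    return df


def write_placed_reads(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.loc[:, PLACED_COLUMNS].to_csv(path, sep="\t", index=False)


def read_bed(path: str | os.PathLike) -> list[tuple[str, int, int, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            name = parts[3] if len(parts) > 3 else ""
            out.append((parts[0], int(parts[1]), int(parts[2]), name))
    return out


def write_bed(intervals: Iterable[tuple[str, int, int, str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")
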