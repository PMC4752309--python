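"""Readers and writers for the standard formats the pipeline touches.

FASTA/FASTQ go through Biopython; tables through pandas.  GFF3 and BED6 are
written line-wise (both are simple TSV dialects; coordinates are converted
from the package's internal 0-based half-open convention at the boundary).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DataError


class FastqRead(NamedTuple):
    """One raw sequencing read (Sanger Phred+33 quality string)."""

    id: str
    seq: str
    qual: str


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    try:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    except (OSError, ValueError) as exc:
        raise DataError(f"cannot read FASTA {path}: {exc}") from exc


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_fastq(path: str | Path) -> list[FastqRead]:
    out: list[FastqRead] = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            quals = rec.letter_annotations["phred_quality"]
            out.append(FastqRead(rec.id, str(rec.seq).upper(),
                                 "".join(chr(q + 33) for q in quals)))
    except (OSError, ValueError) as exc:
        raise DataError(f"cannot read FASTQ {path}: {exc}") from exc
    return out


def write_fastq(path: str | Path, reads: Iterable[FastqRead]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")


def write_tsv(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t")
    except (OSError, ValueError) as exc:
        raise DataError(f"cannot read TSV {path}: {exc}") from exc


def write_bed6(path: str | Path, rows: Iterable[tuple[str, int, int, str, int, str]]) -> None:
    """Write BED6: (chrom, start, end, name, score, strand), 0-based half-open."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def write_gff3(path: str | Path, features: Iterable[dict]) -> None:
    """Write GFF3 features given with 0-based half-open ``start``/``end``.

    Each feature dict needs: seqid, source, type, start, end, score, strand,
    attributes (dict).  Coordinates are emitted 1-based inclusive.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in f["attributes"].items())
            score = f.get("score")
            score_s = "." if score is None else f"{score:.3f}"
            fh.write(
                f"{f['seqid']}\t{f['source']}\t{f['type']}\t{f['start'] + 1}\t{f['end']}\t"
                f"{score_s}\t{f['strand']}\t.\t{attrs}\n"
            )
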