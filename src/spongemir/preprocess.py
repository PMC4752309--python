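"""Read-cleaning cascade for small-RNA libraries.

The stages mirror standard deep small-RNA practice: end-trim low-quality
bases (Phred < 20), clip the 3' sequencing adapter, drop reads shorter than
16 nt, collapse identical sequences, drop sequences observed fewer than five
times per library (sequencing-error suppression at high depth), and finally
remove fragments of known non-coding RNAs (tRNA/rRNA degradation products)
by local alignment against a decoy set.

The decoy filter is a self-contained Smith-Waterman scorer (match +1,
mismatch -2, gap of length g scoring -5 - 2*(g-1)) with a score threshold
chosen so that exact ~20-nt ncRNA fragments are removed while random
sequences of that length essentially never reach it; it plays the role a
BLASTN search against an ncRNA family database plays in full-scale runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import Align

from .config import FilterConfig
from .errors import DataError
from .io import FastqRead, write_tsv
from .sequtil import revcomp, stable_read_id, string_to_phred


@dataclass(frozen=True)
class CollapsedRead:
    """One distinct small-RNA sequence and its library count."""

    sequence: str
    count: int
    id: str

    @classmethod
    def make(cls, sequence: str, count: int) -> "CollapsedRead":
        return cls(sequence=sequence, count=count, id=stable_read_id(sequence))


def trim_read(seq: str, quals: str | Sequence[int], cfg: FilterConfig) -> str | None:
    """Quality- and adapter-trim one read; None if it ends up below min_len.

    Order of operations: 3'-then-5' low-quality end bases are removed, then
    the leftmost exact match of an adapter prefix (minimum overlap
    ``adapter_min_overlap``, no mismatches) and everything 3' of it.
    """
    if len(seq) != len(quals):
        raise DataError("sequence and quality strings differ in length")
    q = string_to_phred(quals) if isinstance(quals, str) else list(quals)
    seq = seq.upper()
    end = len(seq)
    while end > 0 and q[end - 1] < cfg.min_phred:
        end -= 1
    start = 0
    while start < end and q[start] < cfg.min_phred:
        start += 1
    seq = seq[start:end]
    seq = _clip_adapter(seq, cfg.adapter.upper(), cfg.adapter_min_overlap)
    return seq if len(seq) >= cfg.min_len else None


def _clip_adapter(seq: str, adapter: str, min_overlap: int) -> str:
    if not adapter:
        return seq
    n = len(seq)
    for i in range(n - min_overlap + 1):
        overlap = min(len(adapter), n - i)
        if seq[i:i + overlap] == adapter[:overlap]:
            return seq[:i]
    return seq


def collapse_reads(seqs: Iterable[str]) -> list[CollapsedRead]:
    """Collapse a stream of sequences into (sequence, count) records.

    Output is sorted by (count desc, sequence asc) for determinism; counts
    sum to the input size (lossless collapse).
    """
    counts: dict[str, int] = {}
    for s in seqs:
        s = s.upper()
        counts[s] = counts.get(s, 0) + 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [CollapsedRead.make(s, c) for s, c in ordered]


def filter_min_count(collapsed: Sequence[CollapsedRead],
                     cfg: FilterConfig) -> list[CollapsedRead]:
    """Keep sequences observed at least ``min_count`` times; order preserved."""
    return [r for r in collapsed if r.count >= cfg.min_count]


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 1
    a.mismatch_score = -2
    a.open_gap_score = -5
    a.extend_gap_score = -2
    return a


def filter_ncrna(collapsed: Sequence[CollapsedRead],
                 decoys: Sequence[tuple[str, str]],
                 cfg: FilterConfig,
                 ) -> tuple[list[CollapsedRead], list[tuple[CollapsedRead, str]]]:
    """Partition reads into (kept, removed) by best local-alignment score
    against both strands of every decoy; removed reads carry the best-hit
    decoy id (score ties broken by decoy file order, forward strand first).
    """
    if not decoys:
        raise DataError("decoy set is empty")
    aligner = _aligner()
    targets = []
    for name, seq in decoys:
        seq = seq.upper()
        targets.append((name, seq))
        targets.append((name, revcomp(seq)))
    kept: list[CollapsedRead] = []
    removed: list[tuple[CollapsedRead, str]] = []
    for read in collapsed:
        best_score, best_name = -1.0, None
        for name, tseq in targets:
            score = aligner.score(tseq, read.sequence)
            if score > best_score:
                best_score, best_name = score, name
        if best_name is not None and best_score >= cfg.ncrna_min_score:
            removed.append((read, best_name))
        else:
            kept.append(read)
    return kept, removed


@dataclass
class PreprocessResult:
    collapsed: list[CollapsedRead]
    removed_ncrna: list[tuple[CollapsedRead, str]]
    audit: pd.DataFrame


def preprocess_library(reads: Sequence[FastqRead],
                       decoys: Sequence[tuple[str, str]],
                       cfg: FilterConfig) -> PreprocessResult:
    """Run the whole cascade on a raw library, with a per-stage audit trail."""
    audit_rows = []

    def log(stage: str, n_in: int, n_out: int) -> None:
        frac = 0.0 if n_in == 0 else (n_in - n_out) / n_in
        audit_rows.append((stage, n_in, n_out, round(frac, 4)))

    trimmed = [t for r in reads if (t := trim_read(r.seq, r.qual, cfg)) is not None]
    log("trim", len(reads), len(trimmed))
    collapsed = collapse_reads(trimmed)
    log("collapse", len(trimmed), len(collapsed))
    surviving = filter_min_count(collapsed, cfg)
    log("min_count", sum(r.count for r in collapsed), sum(r.count for r in surviving))
    kept, removed = filter_ncrna(surviving, decoys, cfg) if surviving else ([], [])
    log("ncrna", sum(r.count for r in surviving), sum(r.count for r in kept))
    audit = pd.DataFrame(audit_rows,
                         columns=["stage", "reads_in", "reads_out", "fraction_removed"])
    return PreprocessResult(collapsed=kept, removed_ncrna=removed, audit=audit)


def write_collapsed_fasta(path: str | Path, collapsed: Sequence[CollapsedRead]) -> None:
    """miRDeep2-collapsed dialect: header ``>id_count`` with the count embedded."""
    with open(path, "w") as fh:
        for r in collapsed:
            fh.write(f">{r.id}_{r.count}\n{r.sequence}\n")


def read_collapsed_fasta(path: str | Path) -> list[CollapsedRead]:
    out: list[CollapsedRead] = []
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                header = line[1:]
            elif line and header is not None:
                rid, _, count = header.rpartition("_")
                out.append(CollapsedRead(sequence=line.upper(), count=int(count), id=rid))
                header = None
    return out


def write_audit(path: str | Path, audit: pd.DataFrame) -> None:
    write_tsv(path, audit)


__all__ = [
    "CollapsedRead", "PreprocessResult", "trim_read", "collapse_reads",
    "filter_min_count", "filter_ncrna", "preprocess_library",
    "write_collapsed_fasta", "read_collapsed_fasta", "write_audit",
]
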