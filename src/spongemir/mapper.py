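"""Exact/near-exact short-read mapping with a fixed-length k-mer seed index.

Substitution-only, end-to-end alignment of collapsed small-RNA reads against
a small genome — the niche a general-purpose aligner (Bowtie) fills at scale.
Candidate loci come from exact lookups of the read's first and last k-mers;
for ``max_mm >= 1`` the first seed is additionally queried with every
single-substitution variant, which makes the search complete for up to one
mismatch at any read length >= k (an exact two-seed scheme alone is blind to
a mismatch falling in the overlap of the two seeds on reads shorter than 2k).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .config import MapperConfig
from .errors import ConfigError
from .io import write_bed6, write_tsv
from .preprocess import CollapsedRead
from .sequtil import revcomp
from .simdata import Genome


@dataclass
class GenomeIndex:
    """Seed table over both strands of a genome.

    A minus-strand entry ``(scaffold, pos, '-')`` means the reverse
    complement of the genome window starting at ``pos`` equals the seed.
    """

    scaffolds: dict[str, str]
    k: int
    kmer_table: dict[str, list[tuple[str, int, str]]] = field(repr=False,
                                                              default_factory=dict)


@dataclass(frozen=True)
class ReadAlignment:
    """End-to-end placement of one collapsed read (0-based half-open)."""

    read_id: str
    scaffold: str
    start: int
    end: int
    strand: str
    mismatches: int
    count: int


def build_index(genome: Genome, k: int = 12) -> GenomeIndex:
    """Index every k-mer window of every scaffold, both strands; windows
    containing N are skipped."""
    if k < 8:
        raise ConfigError("seed length k must be >= 8")
    if not genome.scaffolds or all(len(s) == 0 for s in genome.scaffolds.values()):
        raise ConfigError("cannot index an empty genome")
    table: dict[str, list[tuple[str, int, str]]] = {}
    for name, seq in genome.scaffolds.items():
        for i in range(len(seq) - k + 1):
            w = seq[i:i + k]
            if "N" in w:
                continue
            table.setdefault(w, []).append((name, i, "+"))
            table.setdefault(revcomp(w), []).append((name, i, "-"))
    return GenomeIndex(scaffolds=dict(genome.scaffolds), k=k, kmer_table=table)


def _mismatches(a: str, b: str, limit: int) -> int:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return mm
    return mm


def _seed_variants(seed: str) -> Iterable[str]:
    yield seed
    for i, base in enumerate(seed):
        for b in "ACGT":
            if b != base:
                yield seed[:i] + b + seed[i + 1:]


def map_read(seq: str, index: GenomeIndex, max_mm: int = 1) -> list[ReadAlignment]:
    """All end-to-end alignments of ``seq`` with at most ``max_mm``
    substitutions, sorted by (scaffold, start, strand)."""
    seq = seq.upper()
    n, k = len(seq), index.k
    if n < k:
        return []
    hits: set[tuple[str, int, str, int]] = set()
    for strand in "+-":
        oriented = seq if strand == "+" else revcomp(seq)
        # candidate genome starts (forward-strand coords) for this orientation
        candidates: set[tuple[str, int]] = set()
        seeds = [(oriented[:k], 0), (oriented[n - k:], n - k)]
        for seed, off in seeds:
            for sc, pos, st in index.kmer_table.get(seed, ()):
                if st == "+":
                    candidates.add((sc, pos - off))
        if max_mm >= 1:
            for variant in _seed_variants(oriented[:k]):
                for sc, pos, st in index.kmer_table.get(variant, ()):
                    if st == "+":
                        candidates.add((sc, pos))
        for sc, start in candidates:
            if start < 0 or start + n > len(index.scaffolds[sc]):
                continue
            window = index.scaffolds[sc][start:start + n]
            mm = _mismatches(oriented, window, max_mm)  # N vs base counts as mismatch
            if mm <= max_mm:
                hits.add((sc, start, strand, mm))
    out = [ReadAlignment(read_id="", scaffold=sc, start=s, end=s + n, strand=st,
                         mismatches=mm, count=1)
           for sc, s, st, mm in hits]
    out.sort(key=lambda a: (a.scaffold, a.start, a.strand))
    return out


@dataclass
class AlignmentSet:
    """Alignments of a collapsed library plus the multi-mapping audit."""

    alignments: list[ReadAlignment]
    discarded_multimappers: list[str]
    unmapped: list[str]

    def mapped_fraction(self, collapsed: Sequence[CollapsedRead]) -> float:
        """Fraction of read copies (count-weighted) that were placed."""
        total = sum(r.count for r in collapsed)
        if total == 0:
            return 0.0
        placed_ids = {a.read_id for a in self.alignments}
        placed = sum(r.count for r in collapsed if r.id in placed_ids)
        return placed / total

    def to_bed6(self, path: str | Path) -> None:
        write_bed6(path, ((a.scaffold, a.start, a.end, a.read_id, a.count, a.strand)
                          for a in self.alignments))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(a.read_id, a.scaffold, a.start, a.end, a.strand, a.mismatches, a.count)
             for a in self.alignments],
            columns=["read_id", "scaffold", "start", "end", "strand",
                     "mismatches", "count"])

    def audit_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [("multimapper_discarded", len(self.discarded_multimappers)),
             ("unmapped", len(self.unmapped))],
            columns=["event", "n_reads"])

    def write_tsv(self, path: str | Path) -> None:
        write_tsv(path, self.to_frame())


def map_library(collapsed: Sequence[CollapsedRead], index: GenomeIndex,
                cfg: MapperConfig | None = None) -> AlignmentSet:
    """Map every collapsed read; reads hitting more than ``max_loci``
    positions are discarded (and logged) as repeat-derived."""
    cfg = cfg or MapperConfig()
    alignments: list[ReadAlignment] = []
    discarded: list[str] = []
    unmapped: list[str] = []
    for read in collapsed:
        hits = map_read(read.sequence, index, cfg.max_mm)
        if not hits:
            unmapped.append(read.id)
        elif len(hits) > cfg.max_loci:
            discarded.append(read.id)
        else:
            alignments.extend(
                ReadAlignment(read_id=read.id, scaffold=a.scaffold, start=a.start,
                              end=a.end, strand=a.strand, mismatches=a.mismatches,
                              count=read.count)
                for a in hits)
    alignments.sort(key=lambda a: (a.scaffold, a.start, a.strand, a.read_id))
    return AlignmentSet(alignments=alignments, discarded_multimappers=discarded,
                        unmapped=unmapped)


__all__ = ["GenomeIndex", "ReadAlignment", "AlignmentSet", "build_index",
           "map_read", "map_library"]
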