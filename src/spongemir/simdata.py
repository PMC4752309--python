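"""Synthetic small-RNA study generator.

Produces a multi-scaffold genome with planted pre-miRNA hairpins, a matching
ground-truth table, a decoy ncRNA set, and a simulated small-RNA FASTQ
library with the statistical structure the discovery pipeline assumes:
dominant mature-arm read stacks with tunable 5'-end homogeneity, minor star
and loop products, ncRNA-degradation and random-genomic background, 3'-ward
quality decay and adapter read-through.

Planted hairpin geometry
------------------------
Each precursor is laid out 5'->3' as ``mature + loop + star``.  The star arm
is the reverse complement of the mature's first ``L-2`` bases followed by two
free 3' bases, so the mature/star duplex carries the canonical 2-nt 3'
overhang on both strands (``overhang_len`` generalises the 2).  Loop bases
are drawn from {A, C} only, so the loop cannot pair internally under
Watson-Crick/GU rules and the planted fold is a clean single stem-loop.
``n_gap_hairpins`` precursors get a run of Ns inserted mid-loop, mimicking an
assembly gap that splits the two arms of a real locus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import SimConfig
from .errors import ConfigError, DataError, PlacementError
from .io import FastqRead, read_fasta, write_fasta, write_fastq, write_tsv
from .sequtil import phred_to_string, revcomp

BASES = np.array(list("ACGT"))
LOOP_BASES = np.array(list("AC"))


@dataclass
class Genome:
    """An ordered set of named scaffolds (DNA, uppercase)."""

    scaffolds: dict[str, str]

    def __len__(self) -> int:
        return sum(len(s) for s in self.scaffolds.values())

    def slice(self, scaffold: str, start: int, end: int, strand: str = "+") -> str:
        """Strand-aware genome slice; minus strand returns the reverse complement."""
        seq = self.scaffolds[scaffold][max(0, start):end]
        return revcomp(seq) if strand == "-" else seq

    def to_fasta(self, path: str | Path) -> None:
        write_fasta(path, self.scaffolds.items())

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        records = read_fasta(path)
        if not records:
            raise DataError(f"genome FASTA {path} contains no sequences")
        return cls(dict(records))


@dataclass
class TruthRecord:
    """Ground truth for one planted hairpin (intervals 0-based half-open)."""

    hairpin_id: str
    scaffold: str
    precursor_interval: tuple[int, int]
    strand: str
    mature_interval: tuple[int, int]
    star_interval: tuple[int, int]
    mature_seq: str
    star_seq: str
    planted_mature_count: int = 0
    planted_star_count: int = 0
    interrupted_by_gap: bool = False


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def generate_genome(cfg: SimConfig) -> Genome:
    """Random genome with the requested scaffold lengths and GC content."""
    if any(L <= 0 for L in cfg.scaffold_lengths):
        raise ConfigError("scaffold lengths must be positive")
    rng = _rng(cfg, 0)
    gc = cfg.gc_fraction
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    scaffolds = {}
    for i, L in enumerate(cfg.scaffold_lengths):
        seq = "".join(BASES[rng.choice(4, size=L, p=probs)])
        scaffolds[f"scaffold_{i + 1}"] = seq
    return Genome(scaffolds)


def _make_precursor(rng: np.random.Generator, cfg: SimConfig, with_gap: bool):
    """Build one precursor sequence plus local mature/star intervals."""
    L = int(rng.integers(cfg.mature_len_range[0], cfg.mature_len_range[1] + 1))
    loop_len = int(rng.integers(cfg.loop_len_range[0], cfg.loop_len_range[1] + 1))
    oh = cfg.overhang_len
    mature = "".join(BASES[rng.integers(0, 4, size=L)])
    # the mature's loop-side overhang bases come from {A,C}, like the loop
    # itself, so the planted duplex is the unique maximum-pairing structure
    # (A/C bases cannot pair with each other under WC+GU rules)
    if oh > 0:
        mature = mature[:L - oh] + "".join(LOOP_BASES[rng.integers(0, 2, size=oh)])
    loop = "".join(LOOP_BASES[rng.integers(0, 2, size=loop_len)])
    if with_gap:
        half = loop_len // 2
        loop = loop[:half] + "N" * cfg.gap_len + loop[half:]
    paired = revcomp(mature[: L - oh]) if oh > 0 else revcomp(mature)
    tail = "".join(BASES[rng.integers(0, 4, size=oh)])
    star = list(paired + tail)
    # star mutations hit the paired region only (the duplex tolerates them)
    if cfg.star_mutations > 0 and len(paired) > 0:
        pos = rng.choice(len(paired), size=min(cfg.star_mutations, len(paired)),
                         replace=False)
        for p in pos:
            alternatives = [b for b in "ACGT" if b != star[p]]
            star[p] = alternatives[int(rng.integers(0, 3))]
    star = "".join(star)
    precursor = mature + loop + star
    mature_local = (0, L)
    star_local = (L + len(loop), len(precursor))
    return precursor, mature_local, star_local, mature, star


def plant_hairpins(genome: Genome, cfg: SimConfig) -> tuple[Genome, list[TruthRecord]]:
    """Embed ``cfg.n_hairpins`` precursors into the genome (both strands).

    Precursors replace genome sequence in place (scaffold lengths are
    preserved).  Placement keeps a margin around each precursor so excision
    windows of neighbouring loci cannot overlap; failure to place within a
    bounded number of retries raises :class:`PlacementError`.
    """
    if cfg.n_hairpins == 0:
        return genome, []
    rng = _rng(cfg, 1)
    margin = 120  # > window_flank + excision padding
    names = list(genome.scaffolds)
    lengths = np.array([len(genome.scaffolds[n]) for n in names], dtype=float)
    scaffold_probs = lengths / lengths.sum()
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    mutable = {n: list(s) for n, s in genome.scaffolds.items()}
    truth: list[TruthRecord] = []
    gap_flags = [i < cfg.n_gap_hairpins for i in range(cfg.n_hairpins)]
    for i, with_gap in enumerate(gap_flags):
        precursor, m_loc, s_loc, mature, star = _make_precursor(rng, cfg, with_gap)
        plen = len(precursor)
        strand = "+" if rng.random() < 0.5 else "-"
        placed = False
        for _ in range(500):
            sc = names[int(rng.choice(len(names), p=scaffold_probs))]
            limit = len(genome.scaffolds[sc]) - plen - margin
            if limit <= margin:
                continue
            p = int(rng.integers(margin, limit))
            if all(p + plen + margin <= a or p >= b + margin for a, b in occupied[sc]):
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place hairpin {i} without overlap after 500 retries"
            )
        occupied[sc].append((p, p + plen))
        inserted = precursor if strand == "+" else revcomp(precursor)
        mutable[sc][p:p + plen] = list(inserted)
        if strand == "+":
            m_iv = (p + m_loc[0], p + m_loc[1])
            s_iv = (p + s_loc[0], p + s_loc[1])
        else:  # transcript runs right-to-left on the genome
            m_iv = (p + plen - m_loc[1], p + plen - m_loc[0])
            s_iv = (p + plen - s_loc[1], p + plen - s_loc[0])
        truth.append(TruthRecord(
            hairpin_id=f"hp{i + 1:03d}",
            scaffold=sc,
            precursor_interval=(p, p + plen),
            strand=strand,
            mature_interval=m_iv,
            star_interval=s_iv,
            mature_seq=mature,
            star_seq=star,
            interrupted_by_gap=with_gap,
        ))
    new_genome = Genome({n: "".join(s) for n, s in mutable.items()})
    return new_genome, truth


def generate_decoys(cfg: SimConfig) -> list[tuple[str, str]]:
    """Random decoy ncRNA set (stands in for tRNA/rRNA families)."""
    rng = _rng(cfg, 3)
    out = []
    for i in range(cfg.n_decoys):
        L = int(rng.integers(cfg.decoy_len_range[0], cfg.decoy_len_range[1] + 1))
        out.append((f"decoy_ncrna_{i + 1:02d}", "".join(BASES[rng.integers(0, 4, size=L)])))
    return out


def _read_at(genome: Genome, scaffold: str, five_prime: int, length: int,
             strand: str) -> str:
    """Read ``length`` bases starting at the transcript 5' position."""
    if strand == "+":
        return genome.slice(scaffold, five_prime, five_prime + length)
    return genome.slice(scaffold, five_prime - length + 1, five_prime + 1, "-")


def _qualities(rng: np.random.Generator, n: int, decay: float) -> str:
    q = 38.0 - decay * np.arange(n) + rng.normal(0.0, 2.0, size=n)
    return phred_to_string(np.clip(np.round(q), 2, 40).astype(int))


_JITTER = np.arange(-3, 4)
_JITTER_P = (4.0 - np.abs(_JITTER)) / (4.0 - np.abs(_JITTER)).sum()


def simulate_reads(genome: Genome, truth: Sequence[TruthRecord], cfg: SimConfig,
                   decoys: Sequence[tuple[str, str]] | None = None,
                   ) -> tuple[list[FastqRead], list[TruthRecord]]:
    """Simulate the small-RNA library.

    Returns the reads and a copy of the truth table with the planted
    error-free mature/star read counts filled in (a read counts as planted
    and error-free when it starts exactly at the true 5' end and carries no
    3' jitter, i.e. its insert equals the planted product exactly).
    """
    if not truth and cfg.background_reads == 0:
        warnings.warn("empty truth table and no background reads: emitting an "
                      "empty library", stacklevel=2)
        return [], list(truth)
    rng = _rng(cfg, 2)
    if decoys is None:
        decoys = generate_decoys(cfg)
    reads: list[FastqRead] = []
    serial = 0

    def emit(seq: str) -> None:
        nonlocal serial
        if "N" in seq:
            return
        if rng.random() < cfg.adapter_readthrough_p:
            seq = seq + cfg.adapter
        serial += 1
        reads.append(FastqRead(f"sim{serial:07d}", seq,
                               _qualities(rng, len(seq), cfg.phred_decay)))

    def product_reads(rec: TruthRecord, interval: tuple[int, int], n: int) -> int:
        """Emit n reads over a planted product; return the error-free count."""
        if strandless_len(interval) == 0 or n == 0:
            return 0
        exact = 0
        g5 = interval[0] if rec.strand == "+" else interval[1] - 1
        true_len = interval[1] - interval[0]
        for _ in range(n):
            shift = 0
            if rng.random() >= cfg.p5_homogeneity:
                shift = int(rng.choice([-2, -1, 1, 2]))
            jitter = int(rng.choice(_JITTER, p=_JITTER_P))
            length = true_len - shift + jitter  # 5' shift moves the start, not the end
            length = max(cfg.read_len_range[0], min(cfg.read_len_range[1], length))
            direction = 1 if rec.strand == "+" else -1
            seq = _read_at(genome, rec.scaffold, g5 + direction * shift, length,
                           rec.strand)
            if len(seq) == length and "N" not in seq:
                if shift == 0 and jitter == 0 and length == true_len:
                    exact += 1
                emit(seq)
        return exact

    def strandless_len(iv: tuple[int, int]) -> int:
        return iv[1] - iv[0]

    mu, sigma = cfg.depth_lognormal
    updated: list[TruthRecord] = []
    for rec in truth:
        mature_n = max(1, int(round(rng.lognormal(mu, sigma))))
        star_n = int(round(cfg.star_fraction * mature_n))
        loop_n = int(round(cfg.loop_fraction * mature_n))
        exact_m = product_reads(rec, rec.mature_interval, mature_n)
        exact_s = product_reads(rec, rec.star_interval, star_n)
        # loop-degradation reads: start inside the loop, run into the 3' arm
        loop_iv = ((rec.mature_interval[1], rec.star_interval[0])
                   if rec.strand == "+"
                   else (rec.star_interval[1], rec.mature_interval[0]))
        for _ in range(loop_n):
            if loop_iv[1] <= loop_iv[0]:
                break
            pos = int(rng.integers(loop_iv[0], loop_iv[1]))
            length = int(rng.integers(16, 23))
            seq = _read_at(genome, rec.scaffold, pos, length, rec.strand)
            if len(seq) == length:
                emit(seq)
        updated.append(replace(rec, planted_mature_count=exact_m,
                               planted_star_count=exact_s))

    # --- background -----------------------------------------------------
    n_decoy_bg = int(round(cfg.background_reads * cfg.background_decoy_fraction))
    n_slice_bg = cfg.background_reads - n_decoy_bg
    if n_decoy_bg > 0 and decoys:
        # a limited set of abundant degradation fragments (tRNA/rRNA-like),
        # so that realistic fragments survive the per-sequence count filter
        n_species = min(cfg.n_decoy_fragment_species, n_decoy_bg)
        frags = []
        for _ in range(n_species):
            did = int(rng.integers(0, len(decoys)))
            dseq = decoys[did][1]
            L = int(rng.integers(18, 27))
            if len(dseq) <= L:
                frags.append(dseq)
            else:
                s = int(rng.integers(0, len(dseq) - L))
                frags.append(dseq[s:s + L])
        weights = rng.lognormal(0.0, 1.0, size=n_species)
        counts = rng.multinomial(n_decoy_bg, weights / weights.sum())
        for frag, c in zip(frags, counts):
            for _ in range(int(c)):
                emit(frag)
    names = list(genome.scaffolds)
    if n_slice_bg > 0 and names:
        lengths = np.array([len(genome.scaffolds[n]) for n in names], dtype=float)
        probs = lengths / lengths.sum()
        for _ in range(n_slice_bg):
            sc = names[int(rng.choice(len(names), p=probs))]
            L = int(rng.integers(16, 29))
            if len(genome.scaffolds[sc]) <= L:
                continue
            s = int(rng.integers(0, len(genome.scaffolds[sc]) - L))
            strand = "+" if rng.random() < 0.5 else "-"
            emit(genome.slice(sc, s, s + L, strand))
    return reads, updated


# ---------------------------------------------------------------------------
# serialisation

_TRUTH_COLUMNS = ["hairpin_id", "scaffold", "precursor_start", "precursor_end",
                  "strand", "mature_start", "mature_end", "star_start", "star_end",
                  "mature_seq", "star_seq", "planted_mature_count",
                  "planted_star_count", "interrupted_by_gap"]


def truth_to_frame(truth: Sequence[TruthRecord]) -> pd.DataFrame:
    rows = [[t.hairpin_id, t.scaffold, *t.precursor_interval, t.strand,
             *t.mature_interval, *t.star_interval, t.mature_seq, t.star_seq,
             t.planted_mature_count, t.planted_star_count, t.interrupted_by_gap]
            for t in truth]
    return pd.DataFrame(rows, columns=_TRUTH_COLUMNS)


def truth_from_frame(df: pd.DataFrame) -> list[TruthRecord]:
    out = []
    for row in df.itertuples(index=False):
        out.append(TruthRecord(
            hairpin_id=row.hairpin_id, scaffold=row.scaffold,
            precursor_interval=(int(row.precursor_start), int(row.precursor_end)),
            strand=row.strand,
            mature_interval=(int(row.mature_start), int(row.mature_end)),
            star_interval=(int(row.star_start), int(row.star_end)),
            mature_seq=row.mature_seq, star_seq=row.star_seq,
            planted_mature_count=int(row.planted_mature_count),
            planted_star_count=int(row.planted_star_count),
            interrupted_by_gap=bool(row.interrupted_by_gap),
        ))
    return out


def simulate_study(cfg: SimConfig, outdir: str | Path | None = None):
    """Run the full generator; optionally write genome/truth/decoys/reads.

    Returns ``(genome, truth, decoys, reads)``.
    """
    genome = generate_genome(cfg)
    genome, truth = plant_hairpins(genome, cfg)
    decoys = generate_decoys(cfg)
    reads, truth = simulate_reads(genome, truth, cfg, decoys)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        genome.to_fasta(outdir / "genome.fasta")
        write_fasta(outdir / "decoys.fasta", decoys)
        write_fastq(outdir / "reads.fastq", reads)
        write_tsv(outdir / "truth.tsv", truth_to_frame(truth))
    return genome, truth, decoys, reads


def check_truth_consistency(genome: Genome, truth: Sequence[TruthRecord]) -> None:
    """Raise DataError unless every non-gap record matches the genome slice."""
    for t in truth:
        if t.interrupted_by_gap:
            continue
        m = genome.slice(t.scaffold, *t.mature_interval, t.strand)
        if m != t.mature_seq:
            raise DataError(f"{t.hairpin_id}: mature_seq does not match genome")
        s = genome.slice(t.scaffold, *t.star_interval, t.strand)
        if s != t.star_seq:
            raise DataError(f"{t.hairpin_id}: star_seq does not match genome")


__all__ = [
    "Genome", "TruthRecord", "generate_genome", "plant_hairpins",
    "generate_decoys", "simulate_reads", "simulate_study",
    "truth_to_frame", "truth_from_frame", "check_truth_consistency",
]
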