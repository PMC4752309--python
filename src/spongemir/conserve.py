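"""Cross-species miRNA conservation analysis.

Mature products of conserved miRNA families are nearly identical between
related species (often at most one base apart), so conservation structure
can be read directly from the sequences: a shift-tolerant ungapped matcher
annotates predictions against a known-miRNA reference, single-linkage
Hamming clustering groups homologous matures within and across species,
per-column conservation profiles reproduce alignment-colouring figures, and
exact-sequence read tallies quantify how much of a library supports each
known mature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import DataError
from .sequtil import hamming, to_dna, to_rna


@dataclass
class MatureMiRNA:
    """A named bona fide mature product (RNA alphabet, lowercase)."""

    name: str
    species: str
    mature_seq: str
    star_seq: str | None = None
    mature_arm: str = "5p"
    mature_count: int = 0
    star_count: int = 0
    known_match: str = ""
    # locus provenance (filled by the discovery stage; absent for fixtures)
    scaffold: str | None = None
    strand: str | None = None
    mature_interval: tuple[int, int] | None = None
    precursor_interval: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.mature_seq = to_rna(self.mature_seq)
        if self.star_seq:
            self.star_seq = to_rna(self.star_seq)
        if self.mature_count < 0 or self.star_count < 0:
            raise DataError("read counts must be non-negative")


@dataclass
class KnownMatch:
    reference: str
    mismatches: int
    shift: int
    overlap: int


def match_known(mature: str, reference: Sequence[tuple[str, str]],
                max_mm: int = 2, max_shift: int = 2) -> KnownMatch | None:
    """Best ungapped match of a mature against a reference set.

    The mature is compared to each reference sequence at every offset in
    [-max_shift, +max_shift] over the overlapping window; the hit with the
    fewest mismatches wins (ties: longest overlap, then reference order).
    Returns None if no comparison reaches ``max_mm`` mismatches or fewer.
    """
    if not reference:
        raise DataError("reference set is empty")
    q = to_dna(mature)
    best: KnownMatch | None = None
    for name, ref in reference:
        r = to_dna(ref)
        for shift in range(-max_shift, max_shift + 1):
            # query position i aligns with reference position i + shift
            lo = max(0, -shift)
            hi = min(len(q), len(r) - shift)
            overlap = hi - lo
            if overlap <= 0:
                continue
            mm = sum(q[i] != r[i + shift] for i in range(lo, hi))
            if mm > max_mm:
                continue
            cand = KnownMatch(reference=name, mismatches=mm, shift=shift,
                              overlap=overlap)
            if best is None or (cand.mismatches, -cand.overlap) < (
                    best.mismatches, -best.overlap):
                best = cand
    return best


@dataclass
class ConservationCluster:
    """A single-linkage group of near-identical matures."""

    members: list[tuple[str, str, str]]  # (species, name, mature_seq)
    max_pairwise_mismatches: int
    shared_across_species: bool
    family: str = ""


def cluster_cross_species(set_a: Iterable[MatureMiRNA],
                          set_b: Iterable[MatureMiRNA],
                          max_mm: int = 1) -> list[ConservationCluster]:
    """Single-linkage clustering of the union of two species' matures.

    Two matures link iff they have equal length and Hamming distance
    <= max_mm (unequal lengths never link).  Cluster family labels follow
    the majority known-match annotation of the members.  Symmetric in the
    two input sets and invariant to input order.
    """
    entries = sorted(list(set_a) + list(set_b),
                     key=lambda m: (m.species, m.name, m.mature_seq))
    n = len(entries)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for i in range(n):
        for j in range(i + 1, n):
            a, b = entries[i].mature_seq, entries[j].mature_seq
            if len(a) == len(b) and hamming(a, b) <= max_mm:
                union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    clusters: list[ConservationCluster] = []
    for root in sorted(groups):
        idx = groups[root]
        members = [(entries[i].species, entries[i].name, entries[i].mature_seq)
                   for i in idx]
        dists = [hamming(entries[i].mature_seq, entries[j].mature_seq)
                 for i in idx for j in idx
                 if i < j and len(entries[i].mature_seq) == len(entries[j].mature_seq)]
        labels = [entries[i].known_match for i in idx if entries[i].known_match]
        family = ""
        if labels:
            family = max(sorted(set(labels)), key=labels.count)
        clusters.append(ConservationCluster(
            members=members,
            max_pairwise_mismatches=max(dists) if dists else 0,
            shared_across_species=len({s for s, _, _ in members}) >= 2,
            family=family))
    return clusters


def n_shared_clusters(clusters: Sequence[ConservationCluster]) -> int:
    return sum(c.shared_across_species for c in clusters)


def arm_dominance(count_5p: int, count_3p: int) -> str:
    """Which hairpin arm contributes more reads: '5p', '3p' or 'tie'."""
    if count_5p < 0 or count_3p < 0:
        raise DataError("arm read counts must be non-negative")
    if count_5p > count_3p:
        return "5p"
    if count_3p > count_5p:
        return "3p"
    return "tie"


@dataclass
class ConservationProfile:
    """Per-column conservation of an equal-length mature alignment.

    Bins follow the usual alignment-shading convention: modal-base fraction
    > 0.80 dark, > 0.60 mid, > 0.40 light, otherwise none.
    """

    sequences: list[str]
    fractions: list[float] = field(default_factory=list)
    bins: list[str] = field(default_factory=list)


def conservation_profile(sequences: Sequence[str],
                         thresholds: tuple[float, float, float] = (0.80, 0.60, 0.40),
                         ) -> ConservationProfile:
    """Column-wise modal-base fraction over >= 2 equal-length sequences.

    Callers pad ragged sets with terminal '-' gaps beforehand; gap characters
    never count as the conserved base.
    """
    seqs = [to_rna(s) for s in sequences]
    if len(seqs) < 2:
        raise DataError("a conservation profile needs at least 2 sequences")
    if len({len(s) for s in seqs}) != 1:
        raise DataError("sequences must have equal length (pad with terminal gaps)")
    dark, mid, light = thresholds
    fractions, bins = [], []
    for col in zip(*seqs):
        bases = [c for c in col if c != "-"]
        frac = max((bases.count(b) for b in set(bases)), default=0) / len(col)
        fractions.append(frac)
        bins.append("dark" if frac > dark else
                    "mid" if frac > mid else
                    "light" if frac > light else "none")
    return ConservationProfile(sequences=seqs, fractions=fractions, bins=bins)


def tally_exact_matches(collapsed, reference: Sequence[tuple[str, str]],
                        ) -> pd.DataFrame:
    """Summed counts of collapsed reads exactly equal to each reference
    mature (U/T-normalised); absent references tally 0."""
    by_seq: dict[str, int] = {}
    for r in collapsed:
        s = to_dna(r.sequence)
        by_seq[s] = by_seq.get(s, 0) + r.count
    rows = [(name, by_seq.get(to_dna(seq), 0)) for name, seq in reference]
    return pd.DataFrame(rows, columns=["reference", "count"])


__all__ = [
    "MatureMiRNA", "KnownMatch", "ConservationCluster", "ConservationProfile",
    "match_known", "cluster_cross_species", "n_shared_clusters", "arm_dominance",
    "conservation_profile", "tally_exact_matches",
]
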