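"""Hairpin discovery from mapped read stacks — the pipeline's core.

Stages: cluster alignments into 5'-coherent read stacks; excise candidate
precursor windows under both arm assumptions (a stack may be the 5p or the
3p product of its hairpin); within each window, scan mature-anchored
precursor spans over a range of loop lengths, fold each span by base-pair
maximisation, and validate the canonical stem-loop geometry; compute the
Dicer processing signature (3' overhang of the mature/star duplex, 5'-end
homogeneity of the stack, duplex pairing fraction); score candidates with a
transparent additive surrogate of the usual discovery score; and select bona
fide miRNAs above the score and signature thresholds.

Windows that contain a run of Ns (assembly gaps splitting a hairpin's two
arms) are excluded from folding and reported separately — such loci are
undiscoverable from mapping patterns even when both arms are present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .config import DiscoveryConfig
from .errors import DataError
from .fold import PairTable, fold_nussinov
from .mapper import ReadAlignment
from .sequtil import to_rna
from .simdata import Genome


# ---------------------------------------------------------------------------
# read stacks

@dataclass
class ReadStack:
    """A pile of alignments sharing (nearly) one 5' coordinate."""

    scaffold: str
    strand: str
    five_prime_position: int          # leftmost 5' coordinate in the cluster
    start_counts: dict[int, int]      # 5' genome position -> summed read count
    total_count: int
    modal_start: int                  # argmax of start_counts (ties: leftmost)
    read_length: int                  # count-weighted modal read length

    @property
    def consistency(self) -> float:
        return five_prime_consistency(self)


def _five_prime(aln: ReadAlignment) -> int:
    return aln.start if aln.strand == "+" else aln.end - 1


def find_stacks(alignments: Sequence[ReadAlignment],
                cfg: DiscoveryConfig) -> list[ReadStack]:
    """Cluster alignments by (scaffold, strand) and 5' start within ±3 nt;
    emit stacks whose count-weighted size reaches ``min_stack_count``."""
    groups: dict[tuple[str, str], list[ReadAlignment]] = {}
    for a in alignments:
        groups.setdefault((a.scaffold, a.strand), []).append(a)
    stacks: list[ReadStack] = []
    for (sc, strand), alns in sorted(groups.items()):
        alns.sort(key=_five_prime)
        cluster: list[ReadAlignment] = []
        for a in alns + [None]:  # sentinel flushes the last cluster
            if cluster and (a is None or _five_prime(a) > _five_prime(cluster[0]) + 3):
                stack = _build_stack(sc, strand, cluster)
                if stack.total_count >= cfg.min_stack_count:
                    stacks.append(stack)
                cluster = []
            if a is not None:
                cluster.append(a)
    stacks.sort(key=lambda s: (s.scaffold, s.strand, s.five_prime_position))
    return stacks


def _build_stack(sc: str, strand: str, alns: list[ReadAlignment]) -> ReadStack:
    starts: dict[int, int] = {}
    lengths: dict[int, int] = {}
    for a in alns:
        p = _five_prime(a)
        starts[p] = starts.get(p, 0) + a.count
        L = a.end - a.start
        lengths[L] = lengths.get(L, 0) + a.count
    modal = min(starts, key=lambda p: (-starts[p], p))
    read_len = min(lengths, key=lambda L: (-lengths[L], L))
    return ReadStack(scaffold=sc, strand=strand,
                     five_prime_position=min(starts),
                     start_counts=starts, total_count=sum(starts.values()),
                     modal_start=modal, read_length=read_len)


def five_prime_consistency(stack: ReadStack) -> float:
    """Fraction of stack reads starting exactly at the modal 5' position."""
    if stack.total_count <= 0:
        raise DataError("five_prime_consistency is undefined for an empty stack")
    return stack.start_counts[stack.modal_start] / stack.total_count


# ---------------------------------------------------------------------------
# precursor windows

@dataclass
class PrecursorWindow:
    """An excised genomic window, transcript-oriented.

    ``seq`` reads 5'->3' on the stack's strand; ``mature_local`` locates the
    stack's read within ``seq``; genome coordinates stay 0-based half-open on
    the forward strand.
    """

    scaffold: str
    strand: str
    start: int
    end: int
    arm_assumption: str           # "5p" | "3p"
    seq: str
    mature_local: tuple[int, int]
    gap_interrupted: bool


def _local(window_start: int, window_end: int, strand: str, gpos: int) -> int:
    """Genome coordinate -> transcript-local coordinate within a window."""
    return gpos - window_start if strand == "+" else (window_end - 1) - gpos


def excise_precursors(stack: ReadStack, genome: Genome,
                      cfg: DiscoveryConfig) -> list[PrecursorWindow]:
    """Two candidate windows per stack (stack as 5p arm, stack as 3p arm),
    clipped to scaffold bounds; windows containing an N run of length >=
    ``gap_run`` are flagged gap_interrupted (not folded, reported)."""
    rl = stack.read_length
    flank = cfg.window_flank
    p = stack.modal_start
    scaffold_len = len(genome.scaffolds[stack.scaffold])
    windows: list[PrecursorWindow] = []
    for arm in ("5p", "3p"):
        up, down = (15, rl + flank) if arm == "5p" else (flank, rl + 15)
        if stack.strand == "+":
            start, end = p - up, p + down
        else:  # transcript runs right-to-left on the genome
            start, end = p - down + 1, p + up + 1
        start, end = max(0, start), min(scaffold_len, end)
        seq = genome.slice(stack.scaffold, start, end, stack.strand)
        m_s = _local(start, end, stack.strand, p)
        windows.append(PrecursorWindow(
            scaffold=stack.scaffold, strand=stack.strand, start=start, end=end,
            arm_assumption=arm, seq=seq, mature_local=(m_s, m_s + rl),
            gap_interrupted="N" * cfg.gap_run in seq))
    return windows


# ---------------------------------------------------------------------------
# hairpin validation

@dataclass
class StemLoopAnnotation:
    accepted: bool
    reason: str                        # "ok" or a rejection code
    mature_arm: str | None = None      # "5p" | "3p"
    star_local: tuple[int, int] | None = None
    loop_local: tuple[int, int] | None = None
    pairing_fraction: float = 0.0


def validate_hairpin(pt: PairTable, mature_local: tuple[int, int],
                     cfg: DiscoveryConfig) -> StemLoopAnnotation:
    """Accept a fold iff it is a single stem-loop with the mature on one arm.

    Rules: exactly one hairpin loop in the structure (no multiloop), the
    mature protrudes at most ``max_mature_loop_overlap`` nt into the loop,
    and at least ``min_pairing_fraction`` of mature bases are paired.  On
    acceptance the star interval is inferred from the pairing partners of the
    mature, extended 2 nt toward its own 3' end (canonical Dicer duplex).
    """
    m_s, m_e = mature_local
    n = len(pt.sequence)
    if not (0 <= m_s < m_e <= n):
        raise DataError("mature interval outside the folded sequence")
    if pt.n_pairs == 0:
        return StemLoopAnnotation(False, "no_stem")
    if pt.n_hairpin_loops() != 1:
        return StemLoopAnnotation(False, "multiloop")
    # the unique hairpin loop: between the innermost pair
    inner_i = max(i for i, j in enumerate(pt.pairs) if 0 <= j and j > i
                  and all(p < 0 for p in pt.pairs[i + 1:j]))
    loop = (inner_i + 1, pt.pairs[inner_i])
    protrusion = max(0, min(m_e, loop[1]) - max(m_s, loop[0]))
    if protrusion > cfg.max_mature_loop_overlap or (m_s < loop[0] and m_e > loop[1]):
        return StemLoopAnnotation(False, "spans_loop")
    arm = "5p" if m_s < loop[0] else "3p"
    # duplex partners only: pairs reaching across the loop to the other arm
    # (pairs into the loop neighbourhood would corrupt the star inference)
    partners = [p for i in range(m_s, m_e) if (p := pt.pairs[i]) >= 0
                and (p >= loop[1] if arm == "5p" else p < loop[0])]
    fraction = len(partners) / (m_e - m_s)
    if not partners or fraction < cfg.min_pairing_fraction:
        return StemLoopAnnotation(False, "weak_duplex", pairing_fraction=fraction)
    star = (min(partners), min(n, max(partners) + 3))
    return StemLoopAnnotation(True, "ok", mature_arm=arm, star_local=star,
                              loop_local=loop, pairing_fraction=fraction)


def overhang_3p(pt: PairTable, mature_local: tuple[int, int],
                star_local: tuple[int, int]) -> tuple[int, int, bool]:
    """3' overhang lengths (mature, star) of the duplex, plus a recessed flag.

    For each duplex strand the overhang is the number of its 3'-terminal
    bases extending beyond the pairing partner of the other strand's 5' end
    (partners of unpaired 5' bases are extrapolated along the duplex
    diagonal).  Blunt ends give 0; recessed ends are reported as 0 with the
    flag set.
    """
    def implied_partner(interval: tuple[int, int]) -> int | None:
        s, e = interval
        for d in range(e - s):
            q = pt.pairs[s + d]
            if q >= 0:
                return q + d
        return None

    recessed = False

    def one(this: tuple[int, int], other: tuple[int, int]) -> int:
        nonlocal recessed
        p = implied_partner(other)
        if p is None:
            recessed = True
            return 0
        oh = (this[1] - 1) - p
        if oh < 0:
            recessed = True
            return 0
        return oh

    return one(mature_local, star_local), one(star_local, mature_local), recessed


# ---------------------------------------------------------------------------
# signature and score

@dataclass
class ProcessingSignature:
    """Per-candidate Dicer-processing metrics."""

    overhang_3p_mature: int
    overhang_3p_star: int
    five_prime_consistency: float
    pairing_fraction: float
    mature_count: int
    star_count: int
    loop_count: int
    score: float = 0.0
    recessed: bool = False


def _overhang_weight(oh: int) -> float:
    return {2: 1.0, 1: 0.5, 3: 0.5}.get(oh, 0.0)


def signature_score(sig: ProcessingSignature, cfg: DiscoveryConfig) -> float:
    """Additive surrogate discovery score:
    w_str*pairing + w_oh*g(overhang) + w_5p*consistency + w_cnt*log10(count+1)
    with g(2)=1, g(1)=g(3)=0.5, 0 otherwise."""
    return (cfg.w_str * sig.pairing_fraction
            + cfg.w_oh * _overhang_weight(sig.overhang_3p_mature)
            + cfg.w_5p * sig.five_prime_consistency
            + cfg.w_cnt * math.log10(sig.mature_count + 1))


# ---------------------------------------------------------------------------
# candidates

@dataclass
class HairpinCandidate:
    """A validated stem-loop with its read support and signature."""

    scaffold: str
    strand: str
    precursor_interval: tuple[int, int]
    precursor_seq: str
    pair_table: PairTable
    mature_interval: tuple[int, int]
    star_interval: tuple[int, int]
    loop_interval: tuple[int, int]
    mature_arm: str
    mature_seq: str
    star_seq: str
    read_partition: dict[str, int] = field(default_factory=dict)
    signature: ProcessingSignature | None = None

    @property
    def score(self) -> float:
        return self.signature.score if self.signature else 0.0


def _to_genome_interval(window: PrecursorWindow, span_offset: int,
                        local: tuple[int, int]) -> tuple[int, int]:
    """Span-local transcript interval -> forward-strand genome interval."""
    ls, le = local[0] + span_offset, local[1] + span_offset
    if window.strand == "+":
        return window.start + ls, window.start + le
    return window.end - le, window.end - ls


def _count_in(alignments: Sequence[ReadAlignment], scaffold: str, strand: str,
              interval: tuple[int, int], tol: int = 2) -> int:
    """Count-weighted reads whose 5' end falls within interval (± tol)."""
    total = 0
    for a in alignments:
        if a.scaffold == scaffold and a.strand == strand:
            p = _five_prime(a)
            if interval[0] - tol <= p < interval[1] + tol:
                total += a.count
    return total


def evaluate_window(window: PrecursorWindow, stack: ReadStack,
                    alignments: Sequence[ReadAlignment],
                    cfg: DiscoveryConfig) -> HairpinCandidate | None:
    """Scan mature-anchored precursor spans inside a window.

    The loop length of a true locus is unknown, so spans
    ``mature + loop + star`` (star length taken equal to the mature's) are
    folded for every loop length in ``loop_scan_range``; the best-scoring
    validated span wins.  A full-window fold is useless here: cardinality
    folding pairs random flanks densely, so precursor bounds must come from
    the read anchor, not from the fold.
    """
    m_s, _ = window.mature_local
    rl_modal = window.mature_local[1] - m_s
    best: HairpinCandidate | None = None
    consistency = five_prime_consistency(stack)
    # the modal read length is a noisy (±1) estimate of the mature 3' end
    # (small-RNA 3' ends are ragged), so the mature length is refined
    # against the fold along with the loop length; the 5' end stays anchored
    for rl in (rl_modal - 1, rl_modal, rl_modal + 1):
        if rl < 16:
            continue
        m_e = m_s + rl
        for loop_len in range(cfg.loop_scan_range[0], cfg.loop_scan_range[1] + 1):
            span_len = 2 * rl + loop_len
            if window.arm_assumption == "5p":
                off = m_s
            else:
                off = m_e - span_len
            if off < 0 or off + span_len > len(window.seq):
                continue
            span = window.seq[off:off + span_len]
            mature_span_local = (m_s - off, m_e - off)
            pt = fold_nussinov(span, cfg.min_loop)
            ann = validate_hairpin(pt, mature_span_local, cfg)
            if not ann.accepted:
                continue
            oh_m, oh_s, recessed = overhang_3p(pt, mature_span_local, ann.star_local)
            star_g = _to_genome_interval(window, off, ann.star_local)
            loop_g = _to_genome_interval(window, off, ann.loop_local)
            prec_g = _to_genome_interval(window, off, (0, span_len))
            star5 = star_g[0] if window.strand == "+" else star_g[1] - 1
            star_count = _count_in(alignments, window.scaffold, window.strand,
                                   (star5, star5 + 1))
            loop_count = _count_in(alignments, window.scaffold, window.strand, loop_g)
            sig = ProcessingSignature(
                overhang_3p_mature=oh_m, overhang_3p_star=oh_s,
                five_prime_consistency=consistency,
                pairing_fraction=ann.pairing_fraction,
                mature_count=stack.total_count, star_count=star_count,
                loop_count=loop_count, recessed=recessed)
            sig.score = signature_score(sig, cfg)
            mature_g = _to_genome_interval(window, off, mature_span_local)
            star_seq = span[ann.star_local[0]:ann.star_local[1]]
            cand = HairpinCandidate(
                scaffold=window.scaffold, strand=window.strand,
                precursor_interval=prec_g, precursor_seq=span, pair_table=pt,
                mature_interval=mature_g, star_interval=star_g, loop_interval=loop_g,
                mature_arm=ann.mature_arm,
                mature_seq=span[mature_span_local[0]:mature_span_local[1]],
                star_seq=star_seq,
                read_partition={"mature": stack.total_count, "star": star_count,
                                "loop": loop_count},
                signature=sig)
            if best is None or cand.score > best.score:
                best = cand
    return best


@dataclass
class DiscoveryResult:
    candidates: list[HairpinCandidate]
    gap_report: pd.DataFrame
    rejection_report: pd.DataFrame


def discover_candidates(alignments: Sequence[ReadAlignment], genome: Genome,
                        cfg: DiscoveryConfig) -> DiscoveryResult:
    """find_stacks -> excise -> fold/validate/score, one best candidate per
    stack; gap-interrupted windows are reported, not folded."""
    stacks = find_stacks(alignments, cfg)
    candidates: list[HairpinCandidate] = []
    gap_rows, rej_rows = [], []
    for stack in stacks:
        windows = excise_precursors(stack, genome, cfg)
        best: HairpinCandidate | None = None
        for w in windows:
            if w.gap_interrupted:
                gap_rows.append((w.scaffold, w.strand, stack.modal_start,
                                 w.start, w.end, w.arm_assumption))
                continue
            cand = evaluate_window(w, stack, alignments, cfg)
            if cand is not None and (best is None or cand.score > best.score):
                best = cand
        if best is not None:
            candidates.append(best)
        else:
            rej_rows.append((stack.scaffold, stack.strand, stack.modal_start,
                             stack.total_count, "no_valid_hairpin"))
    gap_report = pd.DataFrame(
        gap_rows, columns=["scaffold", "strand", "stack_modal_start",
                           "window_start", "window_end", "arm_assumption"])
    rejection_report = pd.DataFrame(
        rej_rows, columns=["scaffold", "strand", "stack_modal_start",
                           "total_count", "reason"])
    return DiscoveryResult(candidates=candidates, gap_report=gap_report,
                           rejection_report=rejection_report)


def select_bona_fide(candidates: Sequence[HairpinCandidate],
                     cfg: DiscoveryConfig, species: str = "sim"):
    """Apply score/consistency/overhang thresholds, then resolve overlapping
    candidates per locus (highest score, then higher mature count, then
    leftmost).  Identical mature sequences at distinct loci are kept as
    separate records."""
    from .conserve import MatureMiRNA  # shared record type

    lo, hi = cfg.overhang_range
    passing = [c for c in candidates
               if c.signature is not None
               and c.score >= cfg.score_threshold
               and c.signature.five_prime_consistency >= cfg.min_five_prime_consistency
               and lo <= c.signature.overhang_3p_mature <= hi
               and (not cfg.require_star_reads or c.signature.star_count >= 1)]
    passing.sort(key=lambda c: (c.scaffold, c.strand, c.precursor_interval))
    kept: list[HairpinCandidate] = []
    for cand in passing:
        # one genomic interval is one locus: a hairpin duplex is a near-
        # palindrome, so reads map to both strands and produce mirrored
        # candidates — overlap resolution therefore ignores strand
        clash = next((k for k in kept
                      if k.scaffold == cand.scaffold
                      and k.precursor_interval[0] < cand.precursor_interval[1]
                      and cand.precursor_interval[0] < k.precursor_interval[1]),
                     None)
        if clash is None:
            kept.append(cand)
            continue
        def rank(c: HairpinCandidate):
            return (-c.score, -c.signature.mature_count, c.precursor_interval[0])
        if rank(cand) < rank(clash):
            kept[kept.index(clash)] = cand
    records = []
    for i, c in enumerate(kept, start=1):
        records.append(MatureMiRNA(
            name=f"{species}-mir-cand-{i}", species=species,
            mature_seq=to_rna(c.mature_seq), star_seq=to_rna(c.star_seq),
            mature_arm=c.mature_arm, mature_count=c.signature.mature_count,
            star_count=c.signature.star_count, known_match="",
            scaffold=c.scaffold, strand=c.strand,
            mature_interval=c.mature_interval,
            precursor_interval=c.precursor_interval,
        ))
    return records, kept


__all__ = [
    "ReadStack", "PrecursorWindow", "StemLoopAnnotation", "ProcessingSignature",
    "HairpinCandidate", "DiscoveryResult", "find_stacks", "five_prime_consistency",
    "excise_precursors", "validate_hairpin", "overhang_3p", "signature_score",
    "evaluate_window", "discover_candidates", "select_bona_fide",
]
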