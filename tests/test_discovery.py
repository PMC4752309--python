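"""Read stacks, precursor excision, hairpin validation, signature scoring."""

import pytest

from spongemir.config import DiscoveryConfig, SimConfig
from spongemir.discovery import (HairpinCandidate, ProcessingSignature,
                                 discover_candidates, excise_precursors,
                                 find_stacks, five_prime_consistency,
                                 overhang_3p, select_bona_fide, signature_score,
                                 validate_hairpin)
from spongemir.errors import DataError
from spongemir.fold import PairTable, fold_nussinov
from spongemir.mapper import ReadAlignment
from spongemir.simdata import Genome, generate_genome, plant_hairpins

CFG = DiscoveryConfig()


def aln(scaffold="s", start=500, length=22, strand="+", count=1, rid="r"):
    return ReadAlignment(read_id=rid, scaffold=scaffold, start=start,
                         end=start + length, strand=strand, mismatches=0,
                         count=count)


class TestFindStacks:
    def test_single_start(self):
        stacks = find_stacks([aln(count=100)], CFG)
        assert len(stacks) == 1
        assert stacks[0].modal_start == 500 and stacks[0].total_count == 100

    def test_nearby_starts_cluster(self):
        stacks = find_stacks([aln(start=500, count=90, rid="a"),
                              aln(start=501, count=10, rid="b")], CFG)
        assert len(stacks) == 1
        assert stacks[0].total_count == 100 and stacks[0].modal_start == 500

    def test_distant_groups_split(self):
        stacks = find_stacks([aln(start=500, count=50, rid="a"),
                              aln(start=700, count=50, rid="b")], CFG)
        assert len(stacks) == 2

    def test_below_min_stack_count_dropped(self):
        assert find_stacks([aln(count=9)], CFG) == []

    def test_minus_strand_uses_read_five_prime(self):
        stacks = find_stacks([aln(start=500, strand="-", count=30, rid="a"),
                              aln(start=499, length=23, strand="-", count=10,
                                  rid="b")], CFG)
        # both reads end at 521 inclusive -> same 5' coordinate on minus strand
        assert len(stacks) == 1 and stacks[0].modal_start == 521


class TestFivePrimeConsistency:
    def test_ninety_ten(self):
        (stack,) = find_stacks([aln(start=500, count=90, rid="a"),
                                aln(start=501, count=10, rid="b")], CFG)
        assert five_prime_consistency(stack) == pytest.approx(0.90)

    def test_single_start_is_one(self):
        (stack,) = find_stacks([aln(count=40)], CFG)
        assert five_prime_consistency(stack) == 1.0

    def test_uniform_four_starts(self):
        reads = [aln(start=500 + i, count=5, rid=f"r{i}") for i in range(4)]
        (stack,) = find_stacks(reads, CFG)
        assert five_prime_consistency(stack) == pytest.approx(0.25)

    def test_empty_stack_undefined(self):
        (stack,) = find_stacks([aln(count=40)], CFG)
        stack.total_count = 0
        with pytest.raises(DataError):
            five_prime_consistency(stack)


class TestExcisePrecursors:
    GENOME = Genome({"s": "A" * 3000})

    def test_window_arithmetic(self):
        (stack,) = find_stacks([aln(start=1000, count=50)], CFG)
        w5, w3 = excise_precursors(stack, self.GENOME, CFG)
        assert (w5.start, w5.end) == (985, 1092)
        assert (w3.start, w3.end) == (930, 1037)

    def test_left_clip_at_scaffold_start(self):
        (stack,) = find_stacks([aln(start=10, count=50)], CFG)
        w5, w3 = excise_precursors(stack, self.GENOME, CFG)
        assert w5.start == 0 and w3.start == 0

    def test_gap_window_flagged(self):
        g = Genome({"s": "A" * 1000 + "C" * 30 + "N" * 12 + "G" * 1000})
        (stack,) = find_stacks([aln(scaffold="s", start=1008, count=50)], CFG)
        windows = excise_precursors(stack, g, CFG)
        assert any(w.gap_interrupted for w in windows)


def build_pair_table(seq, pairing):
    pairs = [-1] * len(seq)
    brackets = ["."] * len(seq)
    for i, j in pairing:
        pairs[i], pairs[j] = j, i
        brackets[i], brackets[j] = "(", ")"
    return PairTable(sequence=seq, pairs=pairs, dot_bracket="".join(brackets))


class TestValidateHairpin:
    def test_planted_hairpin_star_matches_truth(self):
        cfg = SimConfig(seed=9, n_scaffolds=1, scaffold_lengths=[10_000],
                        n_hairpins=4, n_gap_hairpins=0, star_mutations=0)
        genome, truth = plant_hairpins(generate_genome(cfg), cfg)
        for t in truth:
            prec = genome.slice(t.scaffold, *t.precursor_interval, t.strand)
            pt = fold_nussinov(prec, CFG.min_loop)
            L = len(t.mature_seq)
            ann = validate_hairpin(pt, (0, L), CFG)
            assert ann.accepted, ann.reason
            assert ann.mature_arm == "5p"
            star_true = (len(prec) - len(t.star_seq), len(prec))
            assert ann.star_local == star_true

    def test_two_hairpin_loops_rejected_as_multiloop(self):
        pt = build_pair_table("GGAAACCGGAAACC",
                              [(0, 6), (1, 5), (7, 13), (8, 12)])
        ann = validate_hairpin(pt, (0, 6), CFG)
        assert not ann.accepted and ann.reason == "multiloop"

    def test_weak_duplex_rejected(self):
        # stem starts at position 5: only 3 of 10 mature bases are paired
        # while the mature barely touches the loop (protrusion 2)
        pt = build_pair_table("A" * 26, [(5, 20), (6, 19), (7, 18)])
        ann = validate_hairpin(pt, (0, 10), CFG)
        assert not ann.accepted and ann.reason == "weak_duplex"

    def test_unfolded_rejected(self):
        pt = build_pair_table("A" * 20, [])
        assert validate_hairpin(pt, (0, 10), CFG).reason == "no_stem"


class TestOverhang:
    def test_blunt_toy_duplex(self):
        # GGGG AAAA CCCC : 4-pair blunt stem
        pt = build_pair_table("GGGGAAAACCCC",
                              [(0, 11), (1, 10), (2, 9), (3, 8)])
        oh_m, oh_s, recessed = overhang_3p(pt, (0, 4), (8, 12))
        assert (oh_m, oh_s) == (0, 0) and not recessed

    def test_planted_two_nt_overhangs(self):
        cfg = SimConfig(seed=21, n_scaffolds=1, scaffold_lengths=[10_000],
                        n_hairpins=5, n_gap_hairpins=0, star_mutations=0)
        genome, truth = plant_hairpins(generate_genome(cfg), cfg)
        seen = []
        for t in truth:
            prec = genome.slice(t.scaffold, *t.precursor_interval, t.strand)
            pt = fold_nussinov(prec, CFG.min_loop)
            ann = validate_hairpin(pt, (0, len(t.mature_seq)), CFG)
            if ann.accepted:
                seen.append(overhang_3p(pt, (0, len(t.mature_seq)),
                                        ann.star_local)[0])
        assert seen and max(set(seen), key=seen.count) == 2

    def test_recessed_reported_as_zero(self):
        pt = build_pair_table("GGGGAAAACCCCAA",
                              [(0, 11), (1, 10), (2, 9), (3, 8)])
        # the claimed star (0,3) ends one base short of the pairing partner
        # of the mature's 5' end: a recessed 3' end, reported as 0
        oh_m, oh_s, recessed = overhang_3p(pt, (8, 14), (0, 3))
        assert oh_m == 2 and oh_s == 0 and recessed


class TestSignatureScore:
    def sig(self, **kw):
        base = dict(overhang_3p_mature=2, overhang_3p_star=2,
                    five_prime_consistency=0.95, pairing_fraction=0.9,
                    mature_count=999, star_count=0, loop_count=0)
        base.update(kw)
        return ProcessingSignature(**base)

    def test_worked_example(self):
        # 2*0.9 + 1*1 + 2*0.95 + 1*log10(1000) = 7.7
        assert signature_score(self.sig(), CFG) == pytest.approx(7.7)

    def test_zero_components_zero_score(self):
        s = self.sig(overhang_3p_mature=7, five_prime_consistency=0.0,
                     pairing_fraction=0.0, mature_count=0)
        assert signature_score(s, CFG) == 0.0

    def test_monotone_in_overhang_quality(self):
        good = signature_score(self.sig(overhang_3p_mature=2), CFG)
        ok = signature_score(self.sig(overhang_3p_mature=3), CFG)
        bad = signature_score(self.sig(overhang_3p_mature=7), CFG)
        assert good > ok > bad

    def test_monotone_in_each_component(self):
        base = signature_score(self.sig(), CFG)
        assert signature_score(self.sig(pairing_fraction=0.95), CFG) > base
        assert signature_score(self.sig(five_prime_consistency=1.0), CFG) > base
        assert signature_score(self.sig(mature_count=2000), CFG) > base


def make_candidate(scaffold="s", start=100, score=7.0, count=100, strand="+",
                   consistency=0.95, overhang=2, mature="ACGTACGTACGTACGTACGTAC"):
    sig = ProcessingSignature(
        overhang_3p_mature=overhang, overhang_3p_star=2,
        five_prime_consistency=consistency, pairing_fraction=0.9,
        mature_count=count, star_count=2, loop_count=0)
    sig.score = score
    span = (start, start + 56)
    return HairpinCandidate(
        scaffold=scaffold, strand=strand, precursor_interval=span,
        precursor_seq="A" * 56, pair_table=None, mature_interval=(start, start + 22),
        star_interval=(start + 34, start + 56), loop_interval=(start + 22, start + 34),
        mature_arm="5p", mature_seq=mature, star_seq="A" * 22, signature=sig)


class TestSelectBonaFide:
    def test_same_locus_keeps_best(self):
        a = make_candidate(score=7.7, count=200)
        b = make_candidate(score=5.1, count=50)
        records, kept = select_bona_fide([a, b], CFG)
        assert len(records) == 1 and kept[0].score == 7.7

    def test_identical_matures_at_distinct_loci_both_kept(self):
        seq = "auccuguucauccauguaa"
        a = make_candidate(start=100, mature=seq)
        b = make_candidate(start=5000, mature=seq)
        records, _ = select_bona_fide([a, b], CFG)
        assert len(records) == 2
        assert records[0].mature_seq == records[1].mature_seq == seq

    def test_low_consistency_excluded(self):
        c = make_candidate(consistency=0.8)
        records, _ = select_bona_fide([c], CFG)
        assert records == []

    def test_out_of_range_overhang_excluded(self):
        c = make_candidate(overhang=6)
        assert select_bona_fide([c], CFG)[0] == []

    def test_below_score_threshold_excluded(self):
        c = make_candidate(score=4.9)
        assert select_bona_fide([c], CFG)[0] == []


class TestGapBehaviour:
    def test_gap_locus_reported_not_called(self):
        cfg = SimConfig(seed=33, n_scaffolds=1, scaffold_lengths=[9000],
                        n_hairpins=2, n_gap_hairpins=1, background_reads=0)
        genome, truth = plant_hairpins(generate_genome(cfg), cfg)
        gap = next(t for t in truth if t.interrupted_by_gap)
        # synthetic alignments: one clean stack on the gap hairpin's mature
        L = gap.mature_interval[1] - gap.mature_interval[0]
        start = gap.mature_interval[0]
        reads = [ReadAlignment("r1", gap.scaffold, start, start + L,
                               gap.strand, 0, 60)]
        result = discover_candidates(reads, genome, CFG)
        assert len(result.gap_report) >= 1
        assert all(c.mature_interval != gap.mature_interval
                   for c in result.candidates)
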