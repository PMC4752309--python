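"""Synthetic-study generator: determinism, geometry, read statistics."""

import math
import warnings

import numpy as np
import pytest

from spongemir.config import SimConfig
from spongemir.errors import ConfigError
from spongemir.fold import fold_nussinov
from spongemir.sequtil import gc_fraction, revcomp
from spongemir.simdata import (check_truth_consistency, generate_decoys,
                               generate_genome, plant_hairpins, simulate_reads,
                               simulate_study)


class TestGenerateGenome:
    def test_lengths_and_alphabet(self):
        cfg = SimConfig(seed=1, n_scaffolds=1, scaffold_lengths=[1000],
                        gc_fraction=0.5, n_hairpins=0, n_gap_hairpins=0)
        g = generate_genome(cfg)
        (seq,) = g.scaffolds.values()
        assert len(seq) == 1000
        assert set(seq) <= set("ACGT")

    def test_deterministic_per_seed(self, tmp_path):
        cfg = SimConfig(seed=42, n_scaffolds=2, scaffold_lengths=[500, 700],
                        n_hairpins=0, n_gap_hairpins=0)
        a, b = generate_genome(cfg), generate_genome(cfg)
        pa, pb = tmp_path / "a.fa", tmp_path / "b.fa"
        a.to_fasta(pa), b.to_fasta(pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_gc_target_hit_on_long_scaffolds(self):
        cfg = SimConfig(seed=5, n_scaffolds=1, scaffold_lengths=[20_000],
                        gc_fraction=0.35, n_hairpins=0, n_gap_hairpins=0)
        g = generate_genome(cfg)
        assert abs(gc_fraction(next(iter(g.scaffolds.values()))) - 0.35) < 0.05

    def test_degenerate_gc_one(self):
        cfg = SimConfig(seed=1, n_scaffolds=1, scaffold_lengths=[100],
                        gc_fraction=1.0, n_hairpins=0, n_gap_hairpins=0)
        (seq,) = generate_genome(cfg).scaffolds.values()
        assert set(seq) <= set("GC")

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(seed=1, n_scaffolds=1, scaffold_lengths=[0],
                      n_hairpins=0, n_gap_hairpins=0)


class TestPlantHairpins:
    def test_no_hairpins_is_identity(self):
        cfg = SimConfig(seed=2, n_scaffolds=1, scaffold_lengths=[5000],
                        n_hairpins=0, n_gap_hairpins=0)
        g = generate_genome(cfg)
        g2, truth = plant_hairpins(g, cfg)
        assert truth == []
        assert g2.scaffolds == g.scaffolds

    def test_precursor_geometry_and_fold(self):
        # fixed-size duplex: 22 + 12 + 22 = 56 nt, >= 20 of 22 mature bases pair
        cfg = SimConfig(seed=9, n_scaffolds=1, scaffold_lengths=[10_000],
                        n_hairpins=3, n_gap_hairpins=0, star_mutations=0,
                        overhang_len=2, mature_len_range=(22, 22),
                        loop_len_range=(12, 12))
        genome, truth = plant_hairpins(generate_genome(cfg), cfg)
        for t in truth:
            start, end = t.precursor_interval
            assert end - start == 56
            prec = genome.slice(t.scaffold, start, end, t.strand)
            pt = fold_nussinov(prec, 3)
            mature_pairs = sum(1 for i in range(22) if pt.pairs[i] >= 0)
            assert mature_pairs >= 20

    def test_truth_consistency_strand_aware(self, planted_genome):
        _, genome, truth = planted_genome
        check_truth_consistency(genome, truth)  # raises on mismatch

    def test_gap_hairpin_has_n_run(self, planted_genome):
        _, genome, truth = planted_genome
        gapped = [t for t in truth if t.interrupted_by_gap]
        assert len(gapped) == 1
        prec = genome.slice(gapped[0].scaffold, *gapped[0].precursor_interval,
                            gapped[0].strand)
        assert "N" * 10 in prec

    def test_star_is_reverse_complement_of_mature_core(self, planted_genome):
        cfg, _, truth = planted_genome
        for t in truth:
            core = t.mature_seq[: len(t.mature_seq) - cfg.overhang_len]
            assert t.star_seq.startswith(revcomp(core)[: len(core) - cfg.star_mutations])


class TestSimulateReads:
    def test_deterministic(self):
        cfg = SimConfig(seed=11, n_scaffolds=1, scaffold_lengths=[8000],
                        n_hairpins=3, n_gap_hairpins=0, background_reads=200)
        r1 = simulate_study(cfg)[3]
        r2 = simulate_study(cfg)[3]
        assert r1 == r2

    def test_full_homogeneity_gives_single_five_prime(self):
        cfg = SimConfig(seed=13, n_scaffolds=1, scaffold_lengths=[8000],
                        n_hairpins=2, n_gap_hairpins=0, p5_homogeneity=1.0,
                        star_fraction=0.0, loop_fraction=0.0,
                        background_reads=0, adapter_readthrough_p=0.0)
        genome, truth, decoys, reads = simulate_study(cfg)
        for t in truth:
            g5 = (t.mature_interval[0] if t.strand == "+"
                  else t.mature_interval[1] - 1)
            expect5 = genome.slice(
                t.scaffold,
                g5 if t.strand == "+" else g5 - 15,
                g5 + 16 if t.strand == "+" else g5 + 1,
                t.strand)[:16]
            matching = [r for r in reads if r.seq.startswith(expect5)]
            assert matching, f"no reads start at the mature 5' of {t.hairpin_id}"

    def test_zero_star_fraction_means_no_star_reads(self):
        cfg = SimConfig(seed=17, n_scaffolds=1, scaffold_lengths=[8000],
                        n_hairpins=3, n_gap_hairpins=0, star_fraction=0.0,
                        loop_fraction=0.0, background_reads=0,
                        adapter_readthrough_p=0.0, p5_homogeneity=1.0)
        genome, truth, decoys, reads = simulate_study(cfg)
        for t in truth:
            star16 = genome.slice(t.scaffold, *t.star_interval, t.strand)[:16]
            assert not any(r.seq.startswith(star16) for r in reads)
            assert t.planted_star_count == 0

    def test_depth_matches_lognormal_mean(self):
        # total mature-derived reads across 20 hairpins ~ 20 * exp(mu + s^2/2)
        mu, sigma = math.log(200), 0.5
        cfg = SimConfig(seed=19, n_scaffolds=5, scaffold_lengths=[20_000] * 5,
                        n_hairpins=20, n_gap_hairpins=0,
                        depth_lognormal=(mu, sigma), star_fraction=0.0,
                        loop_fraction=0.0, background_reads=0)
        _, truth, _, reads = simulate_study(cfg)
        expected = 20 * math.exp(mu + sigma**2 / 2)
        sd = math.sqrt(20 * (math.exp(sigma**2) - 1)
                       * math.exp(2 * mu + sigma**2))
        assert abs(len(reads) - expected) < 3 * sd

    def test_empty_truth_and_no_background_warns(self):
        cfg = SimConfig(seed=1, n_scaffolds=1, scaffold_lengths=[2000],
                        n_hairpins=0, n_gap_hairpins=0, background_reads=0)
        genome = generate_genome(cfg)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            reads, _ = simulate_reads(genome, [], cfg)
        assert reads == []
        assert any("empty" in str(w.message) for w in caught)

    def test_quality_strings_decay_toward_three_prime(self):
        cfg = SimConfig(seed=23, n_scaffolds=1, scaffold_lengths=[8000],
                        n_hairpins=2, n_gap_hairpins=0, background_reads=100,
                        phred_decay=1.0, adapter_readthrough_p=0.0)
        _, _, _, reads = simulate_study(cfg)
        firsts = np.array([ord(r.qual[0]) - 33 for r in reads])
        lasts = np.array([ord(r.qual[-1]) - 33 for r in reads])
        assert firsts.mean() > lasts.mean() + 5

    def test_adapter_readthrough_present(self):
        cfg = SimConfig(seed=29, n_scaffolds=1, scaffold_lengths=[8000],
                        n_hairpins=2, n_gap_hairpins=0, background_reads=200,
                        adapter_readthrough_p=1.0)
        _, _, _, reads = simulate_study(cfg)
        assert all(cfg.adapter in r.seq for r in reads)

    def test_decoys_deterministic_and_sized(self):
        cfg = SimConfig(seed=31)
        d1, d2 = generate_decoys(cfg), generate_decoys(cfg)
        assert d1 == d2
        assert len(d1) == cfg.n_decoys
        assert all(cfg.decoy_len_range[0] <= len(s) <= cfg.decoy_len_range[1]
                   for _, s in d1)
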