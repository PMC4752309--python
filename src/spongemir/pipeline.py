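"""Pipeline orchestration: preprocess -> map -> discover -> conserve.

Runs the stages on a simulated (or user-supplied) study, writes the standard
artifacts (collapsed FASTA, BED6 alignments, GFF3 precursors, TSV reports)
and keeps a :class:`RunManifest` of per-stage parameters, counts and output
hashes, so identical configurations reproduce byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .config import PipelineConfig
from .conserve import MatureMiRNA, cluster_cross_species, n_shared_clusters
from .discovery import DiscoveryResult, discover_candidates, select_bona_fide
from .errors import ReportError
from .fixtures import load_table2_fixture  # re-exported orchestration surface
from .io import FastqRead, write_fasta, write_gff3, write_tsv
from .mapper import build_index, map_library
from .preprocess import PreprocessResult, preprocess_library, \
    write_collapsed_fasta
from .simdata import Genome, TruthRecord, simulate_study


@dataclass
class StageRecord:
    stage: str
    params: dict
    n_in: int
    n_out: int
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    wall_time: float = 0.0
    valid: bool = True


@dataclass
class RunManifest:
    stages: list[StageRecord] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [(s.stage, s.n_in, s.n_out, round(s.wall_time, 3), s.valid,
                 ";".join(f"{Path(p).name}:{h[:12]}" for p, h in s.outputs.items()))
                for s in self.stages]
        return pd.DataFrame(rows, columns=["stage", "n_in", "n_out",
                                           "wall_time_s", "valid", "outputs"])

    def hash_of(self, stage: str) -> str:
        rec = next(s for s in self.stages if s.stage == stage)
        return hashlib.sha256(
            "".join(sorted(rec.outputs.values())).encode()).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class PipelineResult:
    manifest: RunManifest
    preprocess: PreprocessResult
    discovery: DiscoveryResult
    bona_fide: list[MatureMiRNA]
    kept_candidates: list  # HairpinCandidate per bona_fide record, same order
    truth: list[TruthRecord]
    mapped_fraction: float


def run_pipeline(cfg: PipelineConfig,
                 outdir: str | Path | None = None,
                 genome: Genome | None = None,
                 reads: Sequence[FastqRead] | None = None,
                 decoys: Sequence[tuple[str, str]] | None = None,
                 truth: Sequence[TruthRecord] | None = None,
                 species: str = "sim") -> PipelineResult:
    """Execute the full analysis.

    With no explicit inputs, a synthetic study is generated from
    ``cfg.sim`` first; passing ``genome``/``reads``/``decoys`` runs the same
    stages on external data.  Artifacts are written under ``outdir`` when
    given.
    """
    manifest = RunManifest()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def record(stage: str, params: dict, n_in: int, n_out: int, t0: float,
               files: dict[str, Path]) -> None:
        outputs = {str(p): _sha256(p) for p in files.values() if p.exists()} \
            if out is not None else {}
        manifest.stages.append(StageRecord(
            stage=stage, params=params, n_in=n_in, n_out=n_out,
            outputs=outputs, wall_time=time.monotonic() - t0))

    # --- stage 0: simulate (only when no external inputs were given) -----
    if genome is None or reads is None:
        t0 = time.monotonic()
        genome, truth_list, gen_decoys, reads = simulate_study(
            cfg.sim, outdir=out / "sim" if out else None)
        decoys = decoys if decoys is not None else gen_decoys
        truth = truth_list
        record("simulate", {"seed": cfg.sim.seed,
                            "n_hairpins": cfg.sim.n_hairpins},
               0, len(reads), t0,
               {} if out is None else {"genome": out / "sim" / "genome.fasta",
                                       "reads": out / "sim" / "reads.fastq"})
    truth = list(truth or [])
    decoys = list(decoys or [])

    # --- stage 1: preprocess ---------------------------------------------
    t0 = time.monotonic()
    pre = preprocess_library(reads, decoys, cfg.filters)
    files: dict[str, Path] = {}
    if out is not None:
        files = {"collapsed": out / "collapsed.fasta", "audit": out / "audit.tsv"}
        write_collapsed_fasta(files["collapsed"], pre.collapsed)
        write_tsv(files["audit"], pre.audit)
    record("preprocess",
           {"min_phred": cfg.filters.min_phred, "min_len": cfg.filters.min_len,
            "min_count": cfg.filters.min_count},
           len(reads), sum(r.count for r in pre.collapsed), t0, files)

    # --- stage 2: map ------------------------------------------------------
    t0 = time.monotonic()
    index = build_index(genome, cfg.mapper.k)
    alignments = map_library(pre.collapsed, index, cfg.mapper)
    mapped_fraction = alignments.mapped_fraction(pre.collapsed)
    files = {}
    if out is not None:
        files = {"bed": out / "alignments.bed", "map_audit": out / "map_audit.tsv"}
        alignments.to_bed6(files["bed"])
        write_tsv(files["map_audit"], alignments.audit_frame())
    record("map", {"k": cfg.mapper.k, "max_mm": cfg.mapper.max_mm,
                   "max_loci": cfg.mapper.max_loci},
           sum(r.count for r in pre.collapsed),
           sum(a.count for a in alignments.alignments), t0, files)

    # --- stage 3: discover -------------------------------------------------
    t0 = time.monotonic()
    disc = discover_candidates(alignments.alignments, genome, cfg.discovery)
    bona_fide, kept = select_bona_fide(disc.candidates, cfg.discovery,
                                       species=species)
    files = {}
    if out is not None:
        files = {
            "gff": out / "precursors.gff3",
            "mature": out / "matures.fasta",
            "signatures": out / "signatures.tsv",
            "gaps": out / "gap_report.tsv",
            "rejections": out / "rejections.tsv",
        }
        _write_discovery_outputs(files, kept, bona_fide, disc)
    record("discover", {"score_threshold": cfg.discovery.score_threshold},
           len(disc.candidates), len(bona_fide), t0, files)

    # --- stage 4: conserve (against the bundled known set) ------------------
    t0 = time.monotonic()
    known = load_table2_fixture()
    clusters = cluster_cross_species(bona_fide, known,
                                     max_mm=cfg.conserve.cluster_max_mm)
    files = {}
    if out is not None:
        files = {"clusters": out / "clusters.tsv"}
        write_tsv(files["clusters"], _clusters_frame(clusters))
    record("conserve", {"cluster_max_mm": cfg.conserve.cluster_max_mm},
           len(bona_fide), n_shared_clusters(clusters), t0, files)

    if out is not None:
        write_tsv(out / "manifest.tsv", manifest.to_frame())
    return PipelineResult(manifest=manifest, preprocess=pre, discovery=disc,
                          bona_fide=bona_fide, kept_candidates=kept, truth=truth,
                          mapped_fraction=mapped_fraction)


def _write_discovery_outputs(files: dict[str, Path], kept, bona_fide,
                             disc: DiscoveryResult) -> None:
    gff_features = []
    for rec, cand in zip(bona_fide, kept):
        gff_features.append({
            "seqid": cand.scaffold, "source": "spongemir", "type": "pre_miRNA",
            "start": cand.precursor_interval[0], "end": cand.precursor_interval[1],
            "score": cand.score, "strand": cand.strand,
            "attributes": {"ID": rec.name}})
        for kind, iv in (("mature", cand.mature_interval),
                         ("star", cand.star_interval)):
            gff_features.append({
                "seqid": cand.scaffold, "source": "spongemir", "type": "miRNA",
                "start": iv[0], "end": iv[1], "score": None,
                "strand": cand.strand,
                "attributes": {"ID": f"{rec.name}-{kind}", "Parent": rec.name}})
    write_gff3(files["gff"], gff_features)
    write_fasta(files["mature"], [(r.name, r.mature_seq) for r in bona_fide])
    sig_rows = [(r.name, c.signature.overhang_3p_mature,
                 c.signature.overhang_3p_star,
                 round(c.signature.five_prime_consistency, 4),
                 round(c.signature.pairing_fraction, 4),
                 c.signature.mature_count, c.signature.star_count,
                 c.signature.loop_count, round(c.score, 3))
                for r, c in zip(bona_fide, kept)]
    write_tsv(files["signatures"], pd.DataFrame(
        sig_rows, columns=["name", "overhang_3p_mature", "overhang_3p_star",
                           "five_prime_consistency", "pairing_fraction",
                           "mature_count", "star_count", "loop_count", "score"]))
    write_tsv(files["gaps"], disc.gap_report)
    write_tsv(files["rejections"], disc.rejection_report)


def _clusters_frame(clusters) -> pd.DataFrame:
    rows = [(i + 1, c.family, c.shared_across_species, c.max_pairwise_mismatches,
             ";".join(f"{s}:{n}" for s, n, _ in c.members))
            for i, c in enumerate(clusters)]
    return pd.DataFrame(rows, columns=["cluster", "family", "shared_across_species",
                                       "max_pairwise_mismatches", "members"])


# ---------------------------------------------------------------------------
# paper-style reports

def render_reports(outdir: str | Path,
                   bona_fide: Sequence[MatureMiRNA] | None = None,
                   tally: pd.DataFrame | None = None,
                   profiles: dict[str, list[str]] | None = None) -> list[Path]:
    """Render the three tabular report styles.

    * a bona fide miRNA table (name, mature 5'->3', known match),
    * an exact-match read tally with '-' for zero counts,
    * per-family conservation profile tables.

    Raises :class:`ReportError` when a requested report's artifact is missing.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if bona_fide is None and tally is None and profiles is None:
        raise ReportError("render_reports called with no artifacts at all")
    if bona_fide is not None:
        df = pd.DataFrame(
            [(m.name, m.mature_seq, m.known_match or "") for m in bona_fide],
            columns=["miRNA name", "Predicted mature miRNA (5'-3')",
                     "Matches to known miRNAs"])
        path = out / "bona_fide_table.tsv"
        write_tsv(path, df)
        written.append(path)
    if tally is not None:
        df = tally.copy()
        df["count"] = df["count"].map(lambda c: "-" if c == 0 else str(c))
        path = out / "exact_match_tally.tsv"
        write_tsv(path, df)
        written.append(path)
    if profiles is not None:
        from .conserve import conservation_profile

        rows = []
        for family, seqs in sorted(profiles.items()):
            prof = conservation_profile(seqs)
            for col, (frac, b) in enumerate(zip(prof.fractions, prof.bins)):
                rows.append((family, col + 1, round(frac, 4), b))
        path = out / "conservation_profiles.tsv"
        write_tsv(path, pd.DataFrame(
            rows, columns=["family", "column", "conservation", "bin"]))
        written.append(path)
    return written


def annotate_known(bona_fide: Sequence[MatureMiRNA],
                   reference: Sequence[tuple[str, str]],
                   max_mm: int = 2, max_shift: int = 2) -> None:
    """Fill ``known_match`` on predictions by shift-tolerant matching."""
    from .conserve import match_known

    for rec in bona_fide:
        hit = match_known(rec.mature_seq, reference, max_mm=max_mm,
                          max_shift=max_shift)
        rec.known_match = hit.reference if hit else ""


def recovery_against_truth(bona_fide: Sequence[MatureMiRNA],
                           truth: Sequence[TruthRecord]) -> dict:
    """Compare predictions with the simulator's ground truth.

    A planted (non-gap) hairpin counts as recovered when some bona fide
    record sits on the same scaffold and strand with the exact mature 5'
    genomic position.
    """
    intact = [t for t in truth if not t.interrupted_by_gap]
    gapped = [t for t in truth if t.interrupted_by_gap]

    def five_prime(iv: tuple[int, int], strand: str) -> int:
        return iv[0] if strand == "+" else iv[1] - 1

    pred = {(m.scaffold, m.strand, five_prime(m.mature_interval, m.strand))
            for m in bona_fide if m.mature_interval is not None}
    recovered = [t for t in intact
                 if (t.scaffold, t.strand,
                     five_prime(t.mature_interval, t.strand)) in pred]
    gap_called = [t for t in gapped
                  if (t.scaffold, t.strand,
                      five_prime(t.mature_interval, t.strand)) in pred]
    overhangs = {}
    return {
        "n_planted_intact": len(intact),
        "n_recovered_exact5p": len(recovered),
        "n_gap_planted": len(gapped),
        "n_gap_called_bona_fide": len(gap_called),
        "recovered_ids": [t.hairpin_id for t in recovered],
        **overhangs,
    }


__all__ = ["RunManifest", "StageRecord", "PipelineResult", "run_pipeline",
           "render_reports", "annotate_known", "recovery_against_truth",
           "load_table2_fixture"]
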