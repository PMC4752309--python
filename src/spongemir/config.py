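"""Configuration objects for every pipeline stage.

Each stage owns exactly one config dataclass; :class:`PipelineConfig` nests
them so that no threshold is duplicated between stages.  All configs validate
on construction and raise :class:`~spongemir.errors.ConfigError` on invalid
values, and can round-trip through YAML for the CLI.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigError


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass
class SimConfig:
    """Parameters of the synthetic small-RNA study.

    Defaults describe the standard simulated experiment: a ~100 kb
    multi-scaffold genome carrying 21 planted pre-miRNA hairpins (one of them
    deliberately interrupted by an assembly N-gap), ~200 mature reads per
    hairpin with 95% 5'-end homogeneity, and 10,000 background reads of
    ncRNA-degradation and random-genomic origin.
    """

    seed: int = 0
    n_scaffolds: int = 5
    scaffold_lengths: list[int] = field(default_factory=lambda: [20_000] * 5)
    gc_fraction: float = 0.42
    n_hairpins: int = 21
    mature_len_range: tuple[int, int] = (21, 23)
    loop_len_range: tuple[int, int] = (10, 16)
    star_mutations: int = 0
    overhang_len: int = 2
    depth_lognormal: tuple[float, float] = (5.2983, 0.5)  # mu = ln(200)
    star_fraction: float = 0.10
    loop_fraction: float = 0.02
    p5_homogeneity: float = 0.95
    background_reads: int = 10_000
    background_decoy_fraction: float = 0.7
    n_decoys: int = 20
    decoy_len_range: tuple[int, int] = (70, 120)
    n_decoy_fragment_species: int = 30
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    adapter_readthrough_p: float = 0.3
    phred_decay: float = 0.4
    n_gap_hairpins: int = 1
    gap_len: int = 12
    read_len_range: tuple[int, int] = (16, 40)

    def __post_init__(self) -> None:
        _check(self.n_scaffolds >= 1, "n_scaffolds must be >= 1")
        self.scaffold_lengths = list(self.scaffold_lengths)
        _check(
            len(self.scaffold_lengths) == self.n_scaffolds,
            "scaffold_lengths must have n_scaffolds entries",
        )
        _check(all(L > 0 for L in self.scaffold_lengths), "scaffold lengths must be positive")
        for name in ("gc_fraction", "star_fraction", "loop_fraction", "p5_homogeneity",
                     "background_decoy_fraction", "adapter_readthrough_p"):
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, f"{name} must lie in [0,1]")
        lo, hi = self.mature_len_range
        _check(16 <= lo <= hi <= 30, "mature_len_range must lie within [16,30]")
        lo, hi = self.loop_len_range
        _check(1 <= lo <= hi, "loop_len_range must be positive")
        _check(self.overhang_len >= 0, "overhang_len must be >= 0")
        _check(self.n_hairpins >= 0, "n_hairpins must be >= 0")
        _check(0 <= self.n_gap_hairpins <= self.n_hairpins, "n_gap_hairpins out of range")
        _check(self.star_mutations >= 0, "star_mutations must be >= 0")
        _check(self.background_reads >= 0, "background_reads must be >= 0")
        _check(self.gap_len >= 10, "gap_len must be >= 10 (an N run shorter than 10 is not a gap)")
        _check(self.phred_decay >= 0, "phred_decay must be >= 0")


@dataclass
class FilterConfig:
    """Read-cleaning thresholds.

    ``min_phred``, ``min_len`` and ``min_count`` are the published cleaning
    cascade (end-trim below Phred 20, drop reads under 16 nt, drop sequences
    seen fewer than 5 times per library); ``ncrna_min_score`` is the local-
    alignment score at which a read is called a known-ncRNA fragment, standing
    in for a BLASTN e-value cut-off of about 1e-5 on ~20-nt reads.
    """

    min_phred: int = 20
    min_len: int = 16
    min_count: int = 5
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    adapter_min_overlap: int = 6
    ncrna_min_score: int = 18
    ncrna_evalue_equiv: float = 1e-5

    def __post_init__(self) -> None:
        _check(0 <= self.min_phred <= 41, "min_phred must lie in [0,41]")
        _check(self.min_len >= 1, "min_len must be >= 1")
        _check(self.min_count >= 1, "min_count must be >= 1")
        _check(self.adapter_min_overlap >= 1, "adapter_min_overlap must be >= 1")


@dataclass
class MapperConfig:
    """Seed-and-verify mapping settings (substitution-only, short-read)."""

    k: int = 12
    max_mm: int = 1
    max_loci: int = 5

    def __post_init__(self) -> None:
        _check(self.k >= 8, "seed length k must be >= 8")
        _check(self.max_mm >= 0, "max_mm must be >= 0")
        _check(self.max_loci >= 1, "max_loci must be >= 1")


@dataclass
class DiscoveryConfig:
    """Hairpin-discovery and bona fide selection thresholds.

    ``score_threshold`` mirrors the conventional miRDeep2 cut-off of 5; the
    additive score itself is this package's transparent surrogate (see
    docs/methods.md).  The bona fide criteria (``min_five_prime_consistency``,
    ``overhang_range``) encode the canonical Dicer processing signature and
    are deliberately configurable: they are field-standard placeholders, not
    values lifted from any one study's supplementary criteria.
    """

    min_stack_count: int = 10
    window_flank: int = 70
    min_loop: int = 3
    min_pairing_fraction: float = 0.60
    min_five_prime_consistency: float = 0.90
    overhang_range: tuple[int, int] = (0, 4)
    score_threshold: float = 5.0
    w_str: float = 2.0
    w_oh: float = 1.0
    w_5p: float = 2.0
    w_cnt: float = 1.0
    require_star_reads: bool = False
    max_mature_loop_overlap: int = 2
    loop_scan_range: tuple[int, int] = (4, 30)
    gap_run: int = 5

    def __post_init__(self) -> None:
        _check(self.min_stack_count >= 1, "min_stack_count must be >= 1")
        _check(self.window_flank >= 0, "window_flank must be >= 0")
        _check(self.min_loop >= 0, "min_loop must be >= 0")
        _check(0.0 <= self.min_pairing_fraction <= 1.0, "min_pairing_fraction in [0,1]")
        _check(0.0 <= self.min_five_prime_consistency <= 1.0,
               "min_five_prime_consistency in [0,1]")
        lo, hi = self.overhang_range
        _check(0 <= lo <= hi, "overhang_range must be a non-negative interval")
        lo, hi = self.loop_scan_range
        _check(1 <= lo <= hi, "loop_scan_range must be a positive interval")
        _check(self.gap_run >= 1, "gap_run must be >= 1")


@dataclass
class ConserveConfig:
    """Conservation-analysis settings."""

    known_max_mm: int = 2
    known_max_shift: int = 2
    cluster_max_mm: int = 1
    bin_thresholds: tuple[float, float, float] = (0.80, 0.60, 0.40)

    def __post_init__(self) -> None:
        _check(self.known_max_mm >= 0, "known_max_mm must be >= 0")
        _check(self.known_max_shift >= 0, "known_max_shift must be >= 0")
        _check(self.cluster_max_mm >= 0, "cluster_max_mm must be >= 0")
        d, m, l = self.bin_thresholds
        _check(1.0 >= d > m > l >= 0.0, "bin thresholds must descend within [0,1]")


@dataclass
class PipelineConfig:
    """Top-level configuration: one nested config per stage plus a global seed.

    The global seed fans out to per-stage seeds by fixed offsets so each stage
    is independently reproducible.
    """

    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    mapper: MapperConfig = field(default_factory=MapperConfig)
    discovery: DiscoveryConfig = field(default_factory=DiscoveryConfig)
    conserve: ConserveConfig = field(default_factory=ConserveConfig)

    def __post_init__(self) -> None:
        # single global seed fans out; keep derived seeds below 2**31
        self.sim.seed = (int(self.seed) * 7919 + 1) % (2**31 - 1)

    # -- YAML round-trip -------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        def build(klass, sub: dict[str, Any]):
            names = {f.name for f in fields(klass)}
            unknown = set(sub) - names
            if unknown:
                raise ConfigError(f"unknown {klass.__name__} keys: {sorted(unknown)}")
            return klass(**sub)

        kw: dict[str, Any] = {"seed": int(d.get("seed", 0))}
        for key, klass in (("sim", SimConfig), ("filters", FilterConfig),
                           ("mapper", MapperConfig), ("discovery", DiscoveryConfig),
                           ("conserve", ConserveConfig)):
            sub = dict(d.get(key, {}))
            # YAML has no tuple type; coerce lists for tuple-valued fields
            for f in fields(klass):
                if f.name in sub and isinstance(sub[f.name], list) and "tuple" in str(f.type):
                    sub[f.name] = tuple(sub[f.name])
            kw[key] = build(klass, sub)
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            with open(path) as fh:
                d = yaml.safe_load(fh) or {}
        except OSError as exc:
            raise ConfigError(f"cannot read config file {path}: {exc}") from exc
        if not isinstance(d, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
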