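"""Simulate a small-RNA study and run the full discovery pipeline on it.

Generates a 100 kb genome with 21 planted pre-miRNA hairpins (one split by
an assembly N-gap), simulates ~15,000 reads, and runs cleaning -> mapping ->
hairpin discovery -> bona fide selection.  Prints the per-stage audit and
how many planted matures were recovered at their exact 5' position — the
headline sensitivity figure of the method.
"""

from spongemir.config import PipelineConfig
from spongemir.pipeline import recovery_against_truth, run_pipeline

cfg = PipelineConfig(seed=1)
result = run_pipeline(cfg)

print(result.preprocess.audit.to_string(index=False))
print(f"\nmapped read fraction: {result.mapped_fraction:.3f}")
print(f"bona fide miRNAs called: {len(result.bona_fide)}")

rec = recovery_against_truth(result.bona_fide, result.truth)
print(f"planted matures recovered (exact 5'): "
      f"{rec['n_recovered_exact5p']}/{rec['n_planted_intact']}")
print(f"gap-interrupted hairpins called bona fide: "
      f"{rec['n_gap_called_bona_fide']}/{rec['n_gap_planted']} "
      "(assembly gaps make loci undiscoverable)")

for m in result.bona_fide[:3]:
    print(f"  {m.name}: {m.mature_seq} ({m.mature_count} reads, "
          f"{m.mature_arm} arm)")
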