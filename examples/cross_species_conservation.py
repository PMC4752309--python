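"""Cross-species conservation of the bundled demosponge mature miRNAs.

Clusters the 11 S. carteri and 19 X. testudinaria matures by single-linkage
Hamming distance (<= 1 mismatch, equal lengths only).  Five families are
shared between the two sponges; within a shared family the matures differ
by at most one base, the hallmark of strong mature-arm conservation.
"""

from spongemir.conserve import cluster_cross_species, conservation_profile
from spongemir.fixtures import load_table2_fixture

fx = load_table2_fixture()
sca = [m for m in fx if m.species == "sca"]
xte = [m for m in fx if m.species == "xte"]

clusters = cluster_cross_species(sca, xte, max_mm=1)
shared = [c for c in clusters if c.shared_across_species]
print(f"{len(clusters)} clusters; {len(shared)} shared across both sponges:")
for c in shared:
    names = ", ".join(f"{sp}:{name}" for sp, name, _ in c.members)
    print(f"  {c.family or '(novel)'}: {names} "
          f"(max mismatches {c.max_pairwise_mismatches})")

# per-column conservation of one shared family (alignment-shading style)
fam = next(c for c in shared if c.family == "aqu-miR-2016")
seqs = [s for _, _, s in fam.members]
prof = conservation_profile(seqs)
print(f"\n{fam.family} column conservation "
      f"(dark >80%, mid >60%, light >40%):")
print("  " + seqs[0])
print("  " + "".join({"dark": "D", "mid": "m", "light": "l",
                      "none": "."}[b] for b in prof.bins))
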