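# Methods

## Scope and model

`spongemir` reimplements the deep small-RNA miRNA discovery workflow as a
set of explicit, testable operations. The underlying biological model is
the canonical animal miRNA biogenesis pathway: a genomic locus transcribes
a stem-loop precursor; Drosha and Dicer cuts leave a mature/star duplex
with 2-nt 3' overhangs on both strands; the mature strand accumulates to
far higher copy number than the star, and its 5' end is sharply defined
because Argonaute loading selects it. Sequenced small-RNA reads therefore
pile up in "stacks" with a homogeneous 5' coordinate at genuine miRNA loci,
while degradation products of abundant ncRNAs (tRNA, rRNA) have ragged
ends and no hairpin context. Discovery inverts this model: find stacks,
test the hairpin context, measure the processing signature, and keep loci
that look Dicer-made.

## Read cleaning

Thresholds follow deep-sequencing small-RNA practice: end-trimming below
Phred 20 (end-trim, not sliding window — ends are where quality decays),
exact-prefix 3' adapter clipping with ≥ 6 nt overlap and no mismatches,
discarding reads < 16 nt, and discarding collapsed sequences seen fewer
than 5 times in the library. The count filter is the main error
suppressor: at multi-million-read depth, sequencing errors generate a halo
of low-count neighbours around every abundant sequence.

The ncRNA filter is a self-contained Smith–Waterman scorer (match +1,
mismatch −2, a gap of length *g* scoring −5 − 2(*g* − 1), both strands of
every decoy; implemented with Biopython's `PairwiseAligner`). The score
threshold 18 is calibrated to the read lengths in play: a ~20-nt exact
ncRNA fragment scores ≈ its length (≥ 18), while the best local alignment
of a random 21-mer against an unrelated decoy set stays well below 18. It
plays the role of a BLASTN e-value cut-off (~1e-5) without requiring a
database at test time; candidate sets can still be exported as FASTA for an
external BLASTN run.

## Mapping

Reads are placed end-to-end with substitutions only — small-RNA reads are
too short for indels to be informative — using a k = 12 seed table over
both strands. Exact lookups of the read's first and last k-mer are
complete for 0 mismatches; they are *not* complete for 1 mismatch on reads
shorter than 2k (a substitution in the overlap of the two seeds escapes
both; for a 16-nt read every 12-mer seed covers the centre). The mapper
therefore also queries all 36 single-substitution variants of the first
seed, which restores provable completeness for ≤ 1 mismatch at any read
length ≥ k. Defaults: max 1 mismatch, max 5 loci (beyond which a read is
logged as repeat-derived and dropped). A brute-force all-positions scan
serves as the oracle in the test suite.

## Folding

Hairpin validation needs only the question "is this a single stem-loop
with the mature on one arm?", so the folder maximises the number of nested
base pairs (Watson–Crick + GU wobble; N never pairs; hairpin loops enclose
≥ 3 bases) rather than free energy. The O(n³) fill is a numba kernel; the
traceback prefers pairing the right end of an interval with its outermost
co-optimal partner, which favours long closing stems and is deterministic.
Maximum-cardinality folding is exactly checkable: the test suite and the
acceptance script compare pair counts against exhaustive enumeration over
all nested structures for short sequences.

The trade-off of cardinality folding is that it has no energetic reason to
leave a hairpin loop open: on a random precursor it will happily pair loop
bases against arm bases whenever that does not cost pairs elsewhere. The
simulator is designed so that such rearrangements never gain pairs (see
below), and the validator ignores non-duplex pairs when inferring the star.

## Discovery

Stacks are clusters of alignment 5' ends within ±3 nt (strand-aware; on
the minus strand the 5' end is the alignment's right edge), kept when the
count-weighted size reaches 10. Each stack is excised under both arm
assumptions: a window `[5' − 15, 5' + readlen + 70)` for the stack-as-5p
case and `[5' − 70, 5' + readlen + 15)` for stack-as-3p (mirrored on the
minus strand). Windows containing ≥ 5 consecutive Ns are not folded but
recorded in a gap report: an assembly gap between a hairpin's arms makes
the locus undiscoverable from mapping patterns, a failure mode worth
surfacing explicitly rather than silently dropping.

A full-window fold is useless for precursor delineation here — cardinality
folding pairs the random flanks densely — so precursor bounds come from the
read anchor: spans `mature + loop + star` (star length set to the mature's)
are folded for every loop length in 4–30 and for mature lengths one below
and above the modal read length (small-RNA 3' ends are ragged, so the modal
length is a ±1-noisy estimate of the true mature 3' end; the 5' end stays
fixed). Each span's fold is validated:

* exactly one hairpin loop (no multiloop),
* the mature protrudes ≤ 2 nt into the loop,
* ≥ 60% of mature bases pair across the loop to the other arm.

The star interval is the interval spanned by those duplex partners,
extended 2 nt past its 3' end — the canonical Dicer duplex geometry. The
3' overhang of each duplex strand is the number of its 3'-terminal bases
beyond the pairing partner of the other strand's 5' end (partners of
unpaired 5' bases are extrapolated along the duplex diagonal; negative
values report as 0 with a `recessed` flag). The best-scoring validated
span represents the stack.

### Score

`S = w_str·p + w_oh·g(o) + w_5p·c + w_cnt·log₁₀(mature reads + 1)` with
defaults `w_str = 2, w_oh = 1, w_5p = 2, w_cnt = 1`, pairing fraction *p*,
5' consistency *c*, and `g(2) = 1, g(1) = g(3) = ½, g = 0` otherwise. It
is a transparent additive surrogate for the probabilistic scores of
established discovery tools, monotone in every component, with the
conventional cut-off of 5. Bona fide selection additionally requires
`c ≥ 0.9` and overhang in [0, 4]; both thresholds are configurable because
they stand in for study-specific supplementary criteria rather than a
published constant.

Overlapping candidates on one genomic interval reduce to the best-scoring
(ties: higher mature count, then leftmost) — *ignoring strand*, because a
hairpin duplex is a near-palindrome: reads map to both strands of the
locus and produce mirrored candidates that are one locus, not two.
Identical mature sequences at distinct loci are kept as separate records.

## Conservation

Matching against known mature sets is ungapped with offsets of ±2 nt,
reporting the reference with the fewest mismatches (≤ 2) over the
overlapping window. Cross-species clustering is deliberately stricter and
parameter-free: single-linkage over equal-length matures with Hamming
distance ≤ 1, reflecting how strongly conserved mature arms are between
related species; unequal lengths never link. Arm dominance is a strict
count comparison (ties reported as ties, not resolved). Conservation
profiles bin the per-column modal-base fraction at > 0.80 / > 0.60 /
> 0.40, with terminal alignment gaps never counting as conserved. Exact
tallies sum collapsed-read counts equal to each reference mature after U/T
normalisation, rendering zeros as "–" in reports.

The bundled reference table carries the 30 demosponge bona fide matures
(11 *S. carteri* + 19 *X. testudinaria*, 13 with known-family annotations
across 7 families) and is checksum-verified at load.

## Synthetic studies and what they do (not) show

The generator plants hairpins `mature + loop + star` (star = reverse
complement of the mature minus its overhang, arranged for 2-nt 3' overhangs
on both strands) on random-GC scaffolds, both strands equally likely, then
simulates: mature read counts per hairpin ~ lognormal(ln 200, 0.5); star
and loop reads at 10% and 2% of that; 5' starts exact with probability
0.95, else shifted ±1–2 nt; independent 3' jitter in {−3..3} with
triangular weights P(j) ∝ 4 − |j| (so the modal read length equals the true
mature length, as in real libraries where most 3' ends are exact); 10,000
background reads, 70% drawn from ~30 abundant decoy-ncRNA fragment species
(so that realistic degradation products *survive* the count filter and
must be caught by the decoy filter) and 30% singleton random genome
slices; Phred values starting at 38 with linear 3'-ward decay and Gaussian
jitter; 30% adapter read-through. One hairpin per default study has a
12-nt N run inserted mid-loop, emulating an assembly gap. Everything is
deterministic per seed, and a truth table records intervals, sequences and
exact planted read counts.

Two generator choices exist specifically to keep the planted duplex the
*unique* maximum-pairing structure, since the folder has no energy model:
loop bases and the mature's overhang bases are drawn from {A, C} (A and C
cannot pair with each other under WC+GU rules), and the default star is a
perfect complement (`star_mutations = 0`). With star mutations the
cardinality optimum can shift to loop-harvesting rearrangements and the
single-stem validator then rejects a third of planted loci; mutated-star
behaviour is still exercised in unit tests. Consequently, passing
recovery tests demonstrate the pipeline's bookkeeping, geometry and
thresholds on idealised loci — they do not demonstrate robustness to the
imperfect, bulged duplexes of real genomes, which a free-energy folder
would be needed to handle faithfully.

Default problem sizes (5 × 20 kb scaffolds, 21 hairpins, ~15k reads) were
chosen so a full study simulates, cleans, maps and discovers in a few
seconds while every per-hairpin statistic still has enough reads to be
stable.

## Numerical and design notes

* Coordinates are 0-based half-open internally; GFF3 output converts to
  1-based inclusive. Minus-strand windows and intervals are handled by
  mirroring into transcript orientation at the module boundary.
* Collapse order is (count desc, sequence asc); stack/candidate ordering
  is (scaffold, position); all ties break deterministically, so identical
  configurations reproduce byte-identical artifacts (hashed per stage in
  the run manifest).
* The global seed fans out to per-stage seeds by fixed arithmetic, keeping
  every stage independently reproducible.
* Degenerate inputs are values, not crashes: empty libraries warn and
  return empty artifacts, unmappable reads yield empty alignment lists,
  rejected folds carry reason codes (`multiloop`, `weak_duplex`,
  `spans_loop`, `no_stem`).

## Known limitations

* No free-energy or partition-function folding, no shuffling p-values; the
  validator's single-stem rule is stricter than an energy model would need.
* No paired-end or UMI support; no quality-aware mapping; no indels.
* The decoy filter is only as good as the decoy set; it does not emulate
  Rfam's family models.
* Cross-species clustering requires equal-length matures by design; a
  length-polymorphic homolog would need the shift-tolerant matcher
  instead.
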