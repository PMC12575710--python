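# Methods

This note documents the models and procedures implemented in `kzfptools`,
the parameters that matter, the design choices made where the design was
genuinely open, and the limits of what the synthetic validation shows.

## Zinc-finger detection and fingerprints

Canonical C2H2 fingers are matched by the pattern
`C-x(2,4)-C-x(10,14)-H-x(3,5)-H`, scanned left to right, non-overlapping,
with leftmost-shortest preference (lazy quantifiers).  Spacer characters
may be any residue letter (including X) but never a translation stop, so
fingers cannot chain across stop codons in frame translations.

A second, relaxed pass runs only over unmatched gaps of at least 28
residues lying *between* two canonical fingers.  It admits fingers in
which exactly one of the four coordinating C/H residues is substituted,
and flags them (`flag_ch_mutation`).  Restricting the rescue to
inter-finger gaps mirrors how degenerate fingers occur inside annotated
arrays; isolated degenerate motifs elsewhere in a proteome are far more
often noise than fingers.

Fingerprints are the residues at helix positions −1, +2, +3, +6.  Helical
numbering is operationalized from the first coordinating histidine:
−1 = h1−7, +2 = h1−5, +3 = h1−4, +6 = h1−1.  On a canonical 12-residue
spacer this is identical to indexing the spacer at positions 6, 8, 9, 12
(1-based) — the two formulations are cross-checked against each other on
10,000 random fingers — and it generalizes to non-12 spacers by keeping
the DNA-contacting positions tied to the helix, not to the cysteines.
This choice reproduces the canonical Zif268 finger-1 fingerprint `RDER`.
Structural-residue checks: −3 (h1−9) must be F, +4 (h1−3) must be L, and
−12 is read as the residue two positions before the first cysteine and
must be F or Y; violations set `flag_structural_mutation`.  A spacer too
short to host the fingerprint positions is padded with `-` and flagged.
Fingerprint-array identity is exact ordered string identity of the
concatenated 4-mers; flags never enter identity.

## KRAB detection

KRAB-A is detected by sliding a fixed 42-residue consensus over the
protein and scoring window identity against the full consensus length;
`found` means best score ≥ 0.6 (configurable).  A consensus-identity
detector was chosen over an HMM because it is dependency-free,
transparent, and calibratable: on random 100-mers the 0.6 threshold has a
false-positive rate below 1% (asserted in the test suite).  The cost is
reduced sensitivity to highly diverged KRAB variants, which is acceptable
here because classification feeds a comparative analysis of recent
duplicates.

## Transcript classification

The spliced transcript is translated in three frames; each frame
contributes the ORF starting at its first ATG.  Classes, in precedence
order:

- `coding` — some ORF contains both a KRAB hit and ≥1 finger;
- `other` — some ORF whose own ATG lies within the first 90 nt of the
  transcript has ≥100 codons and ≥1 finger but no KRAB (residual coding
  potential);
- `pseudogene` — a finger array exists in some frame translation but no
  ORF qualifies above (start codon or KRAB lost);
- `non-kzfp` — no finger anywhere.

The 90-nt window and the 100-codon floor operationalize judgements
("missing the start codon", "minimal coding potential") that are
qualitative in manual curation; both are module constants.  A gene with
several transcripts takes the best class among them.  The finger-bearing
(3') exon is located by mapping scanned fingers back through transcript
coordinates and taking the exon holding the majority, ties going 3'-most,
so arrays split by an intron are still attributed sensibly.

## Cluster loci and repertoires

A cluster locus is the interval strictly between two anchor genes — from
1 bp after the upstream anchor's body to 1 bp before the downstream
anchor's — independent of anchor strand or coordinate order.  Repertoires
are multisets of fingerprint-array identity strings of coding genes;
pairwise comparison reports shared arrays (exact identity), per-assembly
unique arrays, and splits shared arrays into equal versus differing copy
number.

## Duplicated gene blocks

All annotated KZFP genes (coding and pseudogene alike) contribute their
3'-exon DNA; using the whole exon rather than the coding region keeps
recently pseudogenized duplicates comparable to their intact parents.
Pairwise distances are 1 − identity of one optimal global alignment
(match +1, mismatch −1, gap open −4, gap extend −1; identity = identical
columns / alignment columns).  Pairwise alignment replaces a multiple
alignment + tree because the block inference consumes only distances, and
pairwise scores are reproducible without an external aligner.

Genes are grouped by single-linkage agglomeration cut at distance 0.05.
The threshold is a free parameter: duplicates diverged at ≤2% sit well
below it and unrelated synthetic genes sit near 0.2–0.3 (they share
finger scaffolds), so recovery is insensitive to the exact cut in a broad
band; the sensitivity is exercised in tests rather than resolved, since
any fixed grouping threshold is a modelling choice.

Blocks are maximal subsequences of group labels, of length ≥3 (the
observed range of real blocks is 3–7 genes), occurring at ≥2
non-overlapping positions in order or exactly reversed (inverted
duplications are biologically expected from recombination between
repeats).  Overlapping candidates are resolved longest-first, ties by
leftmost occurrence; length-2 repeats are reported separately as
partial-duplication candidates, never as blocks.

## TE enrichment and the permutation null

Enrichment of a family in a locus is
`log2[(bp in locus / locus length) / (bp genome-wide / genome length)]`
with annotated bases counted as per-chromosome interval unions and locus
overlap clipped at the boundary.  A family with zero bases in the locus
is reported as absent (sentinel `NA_absent`), not as −∞.  Copy-level
*representation* (fraction of copies inside the locus, fragments sharing
a RepeatMasker join ID counting once) is kept as a separate statistic
because base counts and element counts answer different questions.
Display filtering keeps families with >2% representation and >10 copies
inside the locus.

The permutation null independently re-places every region uniformly on
its own chromosome (length preserved, overlaps permitted), the simplest
null with the standard contract of interval-randomization tests.  The
empirical p-value uses the (1 + k)/(n + 1) correction (n = 1000 by
default) and a Z-score is reported alongside.  Because overlap counts are
small integers, the p-value is discrete and slightly conservative under
heavy ties; the calibration study therefore uses enough regions (300,
with varied lengths) for the count distribution to be fine-grained, and
verifies that the fraction of null datasets at p ≤ 0.05 stays within
0.05 ± 0.02 and that permutation means match exhaustive enumeration on
sub-200-bp instances.

## Duplication-versus-insertion divergence signature

Independently inserted TE copies accumulate divergence independently and
form a continuum; co-duplicated copies inherit their parent's divergence
and pile up at near-identical values.  The signature statistic sorts
divergences and reports maximal runs with consecutive gaps ≤0.5
percentage points and ≥3 members; the contrast is the grouped fraction of
in-locus copies versus the same fraction genome-wide.  Tolerance and
minimum group size are exposed parameters — "nearly identical" has no
canonical value — and the defaults are sensitivity-tested.  The validation
study applies the signature to the LTR/ERV family, where the landscape is
sparse enough (few copies, broad divergence) for the contrast to be
informative; on very dense families a 0.5-point tolerance groups much of
the genome-wide continuum too, which is a known limitation of any
gap-based grouping.

## ChIP-seq peak handling

Peaks overlapping any negative-control peak by ≥1 bp are removed first;
survivors are kept at q ≤ 0.01 and fold enrichment ≥10, relaxing to ≥5
when fewer than 20 peaks remain.  Peak–TE association uses the same
permutation engine per family (independent seeded draws per family);
results report the percentage of peaks overlapping each family, the
permutation Z, the p-value, and a display flag at p < 0.001.  No
multiple-testing correction is applied across families: raw permutation p
with a fixed display cutoff is the convention this analysis follows.

## Contig curation

From PAF alignments: (i) alignments to targets outside the user-supplied
known-chromosome list are discarded, and contigs left with none are
dropped as unplaced; (ii) a contig is assigned to the chromosome of its
single longest alignment block — "longest alignment" read as one block,
not summed bp, with summed bp only as tie-break, then lexicographic
name — and both quantities are reported as evidence; (iii) on each
chromosome, a contig whose merged reference span is fully contained in an
already-retained contig's span, with a strictly smaller longest
alignment, is dropped as nested (processed in decreasing
longest-alignment order; partial overlaps are all retained).  A contig is
reverse-complemented when the majority of its aligned bases on the
assigned chromosome lie on the minus strand — a rule that also covers
mixed-strand contigs, which a bare "aligned to the minus strand"
criterion leaves undefined.  Output is ordered by (chromosome, span
start) and every input contig appears exactly once in the report.
Strand is recomputed only on the assigned chromosome.  Chromosome-level
exclusions (e.g. a fragmented Y) are expressed through the
known-chromosome list, not hard-coded.

## The synthetic-data generator

The generator emulates the structures the analysis assumes, with exact
ground truth:

- **Genes.**  Protein = M-GS-[42-aa KRAB-A consensus]-(linker-finger)×n
  with canonical fingers whose fingerprint residues are drawn at random
  (from an alphabet without C/H); structural positions (−12 Y, −3 F,
  +4 L) are satisfied by construction.  Two exons: exon 1 carries the
  5'UTR + KRAB CDS, exon 2 the finger array, stop and a random 150–300 nt
  3'UTR; the splice sits at a codon boundary; the 5'UTR is generated
  ATG-free.  A configurable fraction (default 0.2) has the start codon
  knocked out (→ pseudogene); a fraction (default 0.15) carries one
  degenerate interior finger (the rescue pass requires canonical
  neighbours, so degenerate end fingers would not round-trip).  Genes are
  placed on random strands.
- **Layout.**  The cluster chromosome holds the two anchor genes with all
  KZFP genes between them at gene gaps of 4–8 kb, and large gene-free
  flanks outside; other chromosomes carry only TEs.  TE copies are
  assigned to chromosomes and to gaps/flanks in proportion to length.
  Coordinates are 0-based half-open internally; emitted GFF3 and
  RepeatMasker `.out` are 1-based inclusive.
- **TEs.**  Three default families (a low-copy young LTR, an older LINE,
  a dense SINE: 18/30/50 copies, consensus 450/800/150 bp).  Per-copy
  target divergence is gamma-distributed (right-skewed, no pile-up at
  zero, matching RepeatMasker divergence landscapes); substitutions are
  Poisson at the target rate, uniform base replacement, no indels, so
  percent divergence equals the substitution fraction.  Recorded
  divergence is the realized value.
- **Duplications.**  A block (never overlapping an anchor) is copied per
  round, mutated at a per-base substitution rate, and inserted at a
  uniform position within a feature-free gap of the locus — never inside
  genes, TEs, or any previous duplication interval, and at least one
  gene-gap away from other duplication intervals so independent blocks
  stay distinguishable in gene order.  Genes and TEs inside the block are
  registered as duplicates with parent links; duplicate gene class and
  fingerprint are re-derived from the final sequence, duplicate TE
  divergence is recomputed against the family consensus.
- **Contigs.**  Breakpoints are uniform over the genome; contigs flip
  with a configurable probability; nested extras are proper sub-intervals
  of existing contigs.  PAF records come from coordinate bookkeeping (one
  perfect block per contig), so curation logic is exercised without
  aligner noise.

Identical configurations produce byte-identical output files.

**What passing tests do and do not show.**  The simulator has no indels,
no TE fragmentation or nesting, no sequencing error, single-isoform
genes, perfect PAF alignments, and toy genome sizes (≈0.9 Mb).  Passing
validation therefore demonstrates that the *rules and statistics* are
implemented correctly and are mutually consistent — not that they are
robust to real assembly artefacts, RepeatMasker fragmentation semantics,
or isoform ambiguity, which real data would add.

## Validation studies and problem sizes

The reproduction script (`scripts/acceptance.py`) and the acceptance
tests run the same studies: 10,000-finger rule agreement; 20 simulations
(24 genes each) for generator round-trip; 20 simulations of 30 genes with
1–3 planted blocks of 3–7 genes (rounds 1–2, post-duplication divergence
≤2%) for block recovery at ±1-gene boundary slack with zero tolerance for
unplanted ≥3-gene blocks; 500 null datasets × 1000 permutations for
calibration; 10 simulations for the duplication signature (3 rounds,
post-rate 0.001, on the block of 4 consecutive genes carrying the most
LTR copies); and 10 simulations for curation.  These sizes keep a full
run to a few minutes while leaving each statistic enough resolution to
fail visibly if a rule regresses.
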