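# kzfptools

Comparative genomics of KRAB-zinc-finger protein (KZFP) gene clusters.

KZFP genes encode transcription factors with a KRAB repressor domain and a
tandem array of C2H2 zinc fingers; they silence transposable elements
(TEs), and their gene clusters are among the fastest-evolving regions of
rodent genomes, expanding by segmental duplication of multi-gene blocks
that carry endogenous retroviruses (ERVs) along with them.  `kzfptools`
implements the analyses this biology calls for, end to end:

- **Zinc-finger annotation** — scan proteins for C2H2 fingers
  (`C-x(2,4)-C-x(10,14)-H-x(3,5)-H`), extract the DNA-contacting
  *fingerprint* residues at helix positions −1, +2, +3, +6 (anchored from
  the first histidine, so the canonical Zif268 finger 1 yields `RDER`),
  flag fingers with mutated C/H anchors or mutated structural residues
  (−12 F/Y, −3 F, +4 L), detect the KRAB-A box by consensus identity, and
  classify transcripts as coding / pseudogene / other / non-KZFP.
- **Cluster comparison** — define a cluster locus as the interval strictly
  between two anchor genes (`Tnfrsf8`/`Miip` by default), count distinct
  fingerprint arrays (exact ordered identity), compare repertoires across
  assemblies, and detect duplicated gene blocks as recurring runs of
  3'-exon similarity groups (single-linkage on pairwise global-alignment
  distances), in direct or inverted orientation.
- **TE statistics** — parse RepeatMasker `.out` files; compute per-family
  locus enrichment `log2[(bp TE in locus / bp locus) / (bp TE genome-wide
  / bp genome)]`; test significance with a from-scratch permutation null
  (uniform re-placement per chromosome, `p = (1+k)/(n+1)`, Z-score
  alongside); compute copy-level representation and the divergence-group
  signature that separates segmental duplication from independent
  insertion.
- **ChIP-seq peaks** — negative-control subtraction, q ≤ 0.01 and
  fold-enrichment ≥ 10 filtering (fallback to ≥ 5 below 20 peaks), and
  per-family peak–TE association Z/p by permutation.
- **Assembly curation** — filter contigs from PAF alignments (keep only
  known chromosomes, assign by longest alignment block, drop nested
  contigs), reverse-complement minus-strand contigs, and emit a
  reference-ordered assembly with a decision report.
- **Synthetic genomes** — a first-class simulator that plants KZFP genes
  (KRAB + in-frame finger arrays across two exons), TE copies with
  per-copy divergence, segmental duplications with parent links, and
  fragmented/flipped/nested contigs, together with machine-readable
  ground truth, so every stage is validated against known answers.

## Worked example

```python
import kzfptools as kt

# simulate a cluster genome with one 4-gene duplication
cfg = kt.SimulationConfig(
    seed=5,
    duplication_events=[kt.DuplicationEvent(2, 5, rounds=2, post_rate=0.01)],
)
sim = kt.build_cluster_genome(cfg)
print(sim.locus)
# ClusterLocus(chromosome='chr1', start=110890, end=332055, ...)

# annotate: class + fingerprint array per gene
table = kt.annotate_genes(sim.kzfp_models, sim.sequences)
print(table["class"].value_counts().to_dict())
# {'coding': 24, 'pseudogene': 8}

# recover the planted block from 3'-exon similarity
from kzfptools.cluster import exon3_sequences, exon3_distances, similarity_groups, detect_blocks
kzfp = sorted(sim.kzfp_models, key=lambda m: m.start)
exons, _ = exon3_sequences(kzfp, sim.sequences)
groups = similarity_groups(exon3_distances(exons), 0.05,
                           positions={m.id: m.start for m in kzfp})
blocks, _ = detect_blocks([(m.id, groups[m.id], (m.start, m.end)) for m in kzfp])
print(blocks[0].block_id, blocks[0].n_genes, len(blocks[0].occurrences))
# block1 4 3
```

The detected block spans the four planted genes and appears three times —
the source plus the two duplicated copies — exactly as registered in
`sim.truth.blocks`.

A command-line interface mirrors the library:

```sh
kzfptools simulate --outdir sim/ --seed 5
kzfptools annotate --genome sim/genome.fa --gff sim/genes.gff3 --out annot.tsv
kzfptools blocks --genes annot.tsv --gff sim/genes.gff3 --genome sim/genome.fa --out blocks.bed
kzfptools enrich --rm sim/repeats.out --locus chr1:110890-332055 --genome chrom.sizes --out enrich.tsv
kzfptools curate --paf sim/alignments.paf --fasta sim/contigs.fa --chroms chr1,chr2,chr3 --out curated/
```

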