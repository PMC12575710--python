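"""Synthetic KZFP cluster genomes with machine-readable ground truth.

The generator emulates the genomic structure the analysis assumes: a
cluster locus flanked by two anchor genes (``Tnfrsf8``/``Miip`` by
default) containing multi-exon KZFP genes whose 3' exon encodes an
in-frame C2H2 zinc-finger array downstream of a KRAB-A box; TE copies of
several families diverged from a per-family consensus; segmental
duplications that co-duplicate genes and TE copies; and
fragmented/flipped/nested contigs with exact-bookkeeping PAF alignments.

Internal coordinates are 0-based half-open; emitted GFF3 and
RepeatMasker .out files are 1-based inclusive.  The substitution model is
uniform base replacement without indels, so percent divergence equals the
substitution fraction.  A fixed configuration (including the seed)
produces byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .cluster import ClusterLocus, locate_cluster
from .curation import PafRecord, write_paf
from .fingers import KRAB_A_CONSENSUS
from .genes import GeneModel, write_gff3
from .repeats import RepeatRecord, write_repeatmasker_out

__all__ = [
    "TEFamilySpec",
    "DuplicationEvent",
    "FragmentationSpec",
    "SimulationConfig",
    "GroundTruth",
    "SyntheticGenome",
    "ContigSet",
    "make_kzfp_gene",
    "build_cluster_genome",
    "apply_segmental_duplication",
    "block_interval_for_genes",
    "fragment_into_contigs",
    "write_fasta",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# one fixed codon per amino acid keeps gene construction deterministic
_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTT", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
    "*": "TAA",
}

#: residues eligible as fingerprint positions (no C/H, which would disturb
#: the finger anchors).
_FP_ALPHABET = "ARNDEQGIKLMSTVWY"

#: residues for anchor-gene proteins (no C/H/M: never a finger).
_PLAIN_ALPHABET = "ADEFGIKLNPQRSTVWY"

_FINGER_LINKER = "TGEKPYK"  # ends Y-K: keeps the -12 F/Y context intact


class LayoutError(ValueError):
    """Planted features do not fit on their chromosome."""


@dataclass
class TEFamilySpec:
    name: str
    te_class: str  # LTR | LINE | SINE | DNA
    consensus_length: int
    copy_number: int
    mean_divergence: float  # percent
    divergence_sd: float    # percent

    def __post_init__(self) -> None:
        if self.consensus_length <= 0 or self.copy_number < 0:
            raise ValueError(f"invalid family spec {self.name}")
        if self.te_class not in ("LTR", "LINE", "SINE", "DNA"):
            raise ValueError(f"unknown TE class {self.te_class}")


@dataclass
class DuplicationEvent:
    """Segmental duplication of the gene block ``first_gene..last_gene``
    (inclusive indices into the planted KZFP gene list)."""

    first_gene: int
    last_gene: int
    rounds: int = 1
    post_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.last_gene < self.first_gene:
            raise ValueError("empty gene range")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if not 0 <= self.post_rate <= 1:
            raise ValueError("post_rate must be in [0, 1]")


@dataclass
class FragmentationSpec:
    n_breakpoints: int = 6
    flip_probability: float = 0.3
    n_nested_extras: int = 2

    def __post_init__(self) -> None:
        if self.n_breakpoints < 0 or self.n_nested_extras < 0:
            raise ValueError("negative fragmentation counts")
        if not 0 <= self.flip_probability <= 1:
            raise ValueError("flip_probability must be in [0, 1]")


def _default_families() -> list[TEFamilySpec]:
    # a young low-copy LTR family, an older LINE, and a dense small SINE;
    # per-copy divergence is gamma-distributed (right-skewed, no pile-up at
    # zero), shaped like murine repeat landscapes at toy scale
    return [
        TEFamilySpec("ERVK10C_MM", "LTR", 450, 18, 10.0, 8.0),
        TEFamilySpec("L1Md_T5", "LINE", 800, 30, 18.0, 8.0),
        TEFamilySpec("B1_Mur4", "SINE", 150, 50, 15.0, 6.0),
    ]


@dataclass
class SimulationConfig:
    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 400_000, "chr2": 250_000, "chr3": 250_000}
    )
    cluster_chromosome: str = "chr1"
    n_kzfp_genes: int = 24
    fingers_per_gene: tuple[int, int] = (4, 10)
    gene_gap_range: tuple[int, int] = (4000, 8000)
    te_families: list[TEFamilySpec] = field(default_factory=_default_families)
    duplication_events: list[DuplicationEvent] = field(default_factory=list)
    anchor_gene_names: tuple[str, str] = ("Tnfrsf8", "Miip")
    fragmentation: FragmentationSpec = field(default_factory=FragmentationSpec)
    pseudogene_fraction: float = 0.2
    degenerate_finger_prob: float = 0.15
    min_gap: int = 60

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        if self.cluster_chromosome not in self.chrom_lengths:
            raise ValueError("cluster chromosome missing from chrom_lengths")
        lo, hi = self.fingers_per_gene
        if lo < 1 or hi < lo:
            raise ValueError("fingers_per_gene range is empty")
        if self.n_kzfp_genes < 0:
            raise ValueError("negative gene count")


# ---------------------------------------------------------------------------
# ground truth registry
# ---------------------------------------------------------------------------

@dataclass
class GeneRecord:
    id: str
    chromosome: str
    start: int  # 0-based half-open
    end: int
    strand: str
    gene_class: str
    fingerprint_key: str
    block_id: str | None = None
    origin: str = "planted"  # planted | duplication
    parent: str | None = None


@dataclass
class TECopyRecord:
    id: str
    family: str
    chromosome: str
    start: int
    end: int
    strand: str
    percent_divergence: float
    origin: str = "insertion"  # insertion | duplication
    parent: str | None = None


@dataclass
class BlockRecord:
    id: str
    chromosome: str
    source: tuple[int, int]
    copies: list[tuple[int, int]]
    gene_ids: list[str]


@dataclass
class ContigRecord:
    name: str
    chromosome: str
    start: int
    end: int
    strand: str
    nested_in: str | None = None


@dataclass
class GroundTruth:
    """Registry of everything planted in a synthetic genome."""

    genes: list[GeneRecord] = field(default_factory=list)
    te_copies: list[TECopyRecord] = field(default_factory=list)
    blocks: list[BlockRecord] = field(default_factory=list)
    contigs: list[ContigRecord] = field(default_factory=list)

    def validate(self) -> None:
        by_id = {t.id for t in self.te_copies}
        for t in self.te_copies:
            if t.origin == "duplication" and t.parent not in by_id:
                raise ValueError(f"duplicated TE {t.id} lacks a parent")
        for b in self.blocks:
            for cs, ce in b.copies:
                if cs < b.source[1] and ce > b.source[0]:
                    raise ValueError(f"block {b.id}: copy overlaps source")

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        pd.DataFrame([vars(g) for g in self.genes]).to_csv(
            outdir / "truth_genes.tsv", sep="\t", index=False
        )
        pd.DataFrame([vars(t) for t in self.te_copies]).to_csv(
            outdir / "truth_te_copies.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            [
                {
                    "id": b.id,
                    "chromosome": b.chromosome,
                    "source_start": b.source[0],
                    "source_end": b.source[1],
                    "copies": ";".join(f"{s}-{e}" for s, e in b.copies),
                    "gene_ids": ";".join(b.gene_ids),
                }
                for b in self.blocks
            ]
        ).to_csv(outdir / "truth_blocks.tsv", sep="\t", index=False)
        pd.DataFrame([vars(c) for c in self.contigs]).to_csv(
            outdir / "truth_contigs.tsv", sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# gene construction
# ---------------------------------------------------------------------------

class KzfpGene(NamedTuple):
    dna: str
    protein: str
    model: GeneModel  # coordinates relative to the gene's own DNA, '+' strand
    fingerprints: list[str]


def _codons(protein: str) -> str:
    return "".join(_CODON[a] for a in protein)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def _random_dna_no_atg(rng: np.random.Generator, n: int) -> str:
    seq = _random_dna(rng, n)
    while "ATG" in seq:
        seq = _random_dna(rng, n)
    return seq


def _finger_peptide(rng: np.random.Generator, fp: str) -> str:
    # spacer positions (1-based): 4 = -3 (F), 6/8/9/12 = fingerprint,
    # 10 = +4 (L); remaining spacer positions are fixed scaffold residues
    spacer = f"GKSFS{fp[0]}S{fp[1]}{fp[2]}LQ{fp[3]}"
    return f"CPEC{spacer}HQRTH"


def make_kzfp_gene(
    rng: np.random.Generator,
    n_fingers: int,
    degenerate_positions: list[int] | tuple[int, ...] = (),
    knockout_start: bool = False,
    utr3_length: int | None = None,
) -> KzfpGene:
    """Construct one synthetic KZFP gene.

    The protein is M-GS-[KRAB-A consensus]-(linker-finger)*n-tail with
    canonical C-X2-C-X12-H-X3-H fingers; fingerprint residues are drawn
    randomly.  Fingers listed in ``degenerate_positions`` (0-based) carry
    one C->other-residue substitution.  ``knockout_start`` removes the
    start codon (ATG -> CTG), which demotes the transcript to a pseudogene.

    The gene has two exons: exon 1 carries the 5'UTR and the KRAB-coding
    CDS, exon 2 the finger array, stop codon and a random 3'UTR.
    """
    if n_fingers < 1:
        raise ValueError("a KZFP gene needs at least one zinc finger")
    degenerate = set(int(i) for i in degenerate_positions)
    if degenerate and (min(degenerate) < 0 or max(degenerate) >= n_fingers):
        raise ValueError("degenerate finger index out of range")

    fingerprints = [
        "".join(
            _FP_ALPHABET[i] for i in rng.integers(0, len(_FP_ALPHABET), size=4)
        )
        for _ in range(n_fingers)
    ]
    finger_parts = []
    for i, fp in enumerate(fingerprints):
        pep = _finger_peptide(rng, fp)
        if i in degenerate:
            which = int(rng.integers(0, 2))  # substitute c1 or c2
            sub = "SRGA"[int(rng.integers(0, 4))]
            idx = 0 if which == 0 else 3
            pep = pep[:idx] + sub + pep[idx + 1 :]
        finger_parts.append(_FINGER_LINKER + pep)

    head = "MGS" + KRAB_A_CONSENSUS          # exon 1 CDS
    tail_prot = "".join(finger_parts) + "GSQ"  # exon 2 CDS (minus stop)
    protein = head + tail_prot

    utr5 = _random_dna_no_atg(rng, 30)
    cds1 = _codons(head)
    if knockout_start:
        cds1 = "C" + cds1[1:]
    intron = "GT" + _random_dna(rng, int(rng.integers(80, 151))) + "AG"
    utr3 = _random_dna(
        rng, int(rng.integers(150, 301)) if utr3_length is None else utr3_length
    )
    cds2 = _codons(tail_prot) + _CODON["*"]

    exon1 = utr5 + cds1
    exon2 = cds2 + utr3
    dna = exon1 + intron + exon2
    e2_start = len(exon1) + len(intron)
    model = GeneModel(
        id="",
        chromosome="",
        strand="+",
        exons=[(0, len(exon1)), (e2_start, len(dna))],
        cds=[(len(utr5), len(exon1)), (e2_start, e2_start + len(cds2))],
        zf_exon_index=1,
    )
    return KzfpGene(dna, protein, model, fingerprints)


def _make_anchor_gene(rng: np.random.Generator) -> tuple[str, GeneModel]:
    body = "".join(
        _PLAIN_ALPHABET[i]
        for i in rng.integers(0, len(_PLAIN_ALPHABET), size=60)
    )
    dna = _random_dna_no_atg(rng, 20) + _codons("M" + body) + _CODON["*"] + _random_dna(rng, 40)
    model = GeneModel(
        id="", chromosome="", strand="+", exons=[(0, len(dna))],
        cds=[(20, 20 + 3 * 62)],
    )
    return dna, model


def _place_model(
    model: GeneModel, gene_id: str, chrom: str, pos: int, strand: str,
    length: int, attrs: dict | None = None,
) -> GeneModel:
    """Map a gene-relative model onto the genome at ``pos``/``strand``."""
    def map_iv(s: int, e: int) -> tuple[int, int]:
        if strand == "+":
            return pos + s, pos + e
        return pos + length - e, pos + length - s

    return GeneModel(
        id=gene_id,
        chromosome=chrom,
        strand=strand,
        exons=[map_iv(s, e) for s, e in model.exons],
        cds=[map_iv(s, e) for s, e in model.cds] if model.cds else None,
        gene_class=model.gene_class,
        zf_exon_index=model.zf_exon_index,
        attributes=attrs or {},
    )


def _revcomp(seq: str) -> str:
    comp = str.maketrans("ACGTN", "TGCAN")
    return seq.translate(comp)[::-1]


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGenome:
    config: SimulationConfig
    sequences: dict[str, str]
    models: list[GeneModel]        # anchors + KZFP genes (+ duplicates)
    truth: GroundTruth
    consensus: dict[str, str]
    locus: ClusterLocus
    _n_blocks: int = 0

    @property
    def kzfp_models(self) -> list[GeneModel]:
        anchors = set(self.config.anchor_gene_names)
        return [
            m for m in self.models
            if m.attributes.get("Name", m.id) not in anchors
        ]

    def repeat_records(self) -> list[RepeatRecord]:
        fam_class = {f.name: f.te_class for f in self.config.te_families}
        recs = []
        for t in self.te_copies_sorted():
            recs.append(
                RepeatRecord(
                    chromosome=t.chromosome,
                    begin=t.start + 1,
                    end=t.end,
                    strand=t.strand,
                    family=t.family,
                    class_family=fam_class.get(t.family, "Unknown"),
                    percent_divergence=round(t.percent_divergence, 1),
                    join_id=t.id,
                    score=1000,
                )
            )
        return recs

    def te_copies_sorted(self) -> list[TECopyRecord]:
        order = list(self.sequences)
        return sorted(
            self.truth.te_copies,
            key=lambda t: (order.index(t.chromosome), t.start),
        )

    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.sequences, outdir / "genome.fa")
        write_gff3(sorted(self.models, key=lambda m: (m.chromosome, m.start)),
                   outdir / "genes.gff3")
        write_repeatmasker_out(
            self.repeat_records(), outdir / "repeats.out",
            chrom_lengths=self.chrom_lengths(),
            consensus_lengths={f: len(s) for f, s in self.consensus.items()},
        )
        self.truth.write(outdir)

    # -- coordinate bookkeeping -------------------------------------------
    def _shift(self, chrom: str, pos: int, offset: int) -> None:
        """Shift every recorded coordinate >= pos on ``chrom`` by offset."""
        def mv(x: int) -> int:
            return x + offset if x >= pos else x

        for m in self.models:
            if m.chromosome != chrom:
                continue
            m.exons = [(mv(s), mv(e)) for s, e in m.exons]
            if m.cds:
                m.cds = [(mv(s), mv(e)) for s, e in m.cds]
        for g in self.truth.genes:
            if g.chromosome == chrom:
                g.start, g.end = mv(g.start), mv(g.end)
        for t in self.truth.te_copies:
            if t.chromosome == chrom:
                t.start, t.end = mv(t.start), mv(t.end)
        for b in self.truth.blocks:
            if b.chromosome == chrom:
                b.source = (mv(b.source[0]), mv(b.source[1]))
                b.copies = [(mv(s), mv(e)) for s, e in b.copies]
        if self.locus.chromosome == chrom and pos >= self.locus.start0:
            new_end = self.locus.end + offset if pos < self.locus.end0 else self.locus.end
            self.locus = replace(self.locus, end=new_end)


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _draw_divergence(rng: np.random.Generator, fam: TEFamilySpec) -> float:
    """Per-copy target divergence (percent), gamma with the configured
    mean and spread; degenerates to the exact mean when the spread is 0."""
    if fam.divergence_sd <= 0:
        return fam.mean_divergence
    shape = (fam.mean_divergence / fam.divergence_sd) ** 2
    scale = fam.divergence_sd**2 / fam.mean_divergence
    return float(rng.gamma(shape, scale))


def _mutate(
    seq: str, rng: np.random.Generator, n_subs: int
) -> tuple[str, int]:
    """Substitute at ``n_subs`` distinct positions (capped at len)."""
    n = min(n_subs, len(seq))
    if n == 0:
        return seq, 0
    pos = rng.choice(len(seq), size=n, replace=False)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    for p in pos:
        cur = arr[p]
        choices = _BASES[_BASES != cur]
        arr[p] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode(), n


def _mutate_rate(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    mask = rng.random(len(seq)) < rate
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    for p in np.nonzero(mask)[0]:
        cur = arr[p]
        choices = _BASES[_BASES != cur]
        arr[p] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


def build_cluster_genome(config: SimulationConfig) -> SyntheticGenome:
    """Build the genome, annotations, and ground truth for one simulation.

    The cluster chromosome carries the two anchor genes with all KZFP
    genes between them; TE copies are spread over all chromosomes in
    proportion to length.  Configured duplication events are applied after
    layout.  Raises :class:`LayoutError` if the planted features do not
    fit.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    consensus = {f.name: _random_dna(rng, f.consensus_length) for f in cfg.te_families}

    # --- plant genes ------------------------------------------------------
    anchors = []
    for name in cfg.anchor_gene_names:
        dna, model = _make_anchor_gene(rng)
        anchors.append((name, dna, model))

    lo, hi = cfg.fingers_per_gene
    genes: list[tuple[str, KzfpGene, str]] = []  # (id, parts, strand)
    for i in range(cfg.n_kzfp_genes):
        n_fingers = int(rng.integers(lo, hi + 1))
        degenerate: list[int] = []
        if n_fingers >= 3 and rng.random() < cfg.degenerate_finger_prob:
            degenerate = [int(rng.integers(1, n_fingers - 1))]
        knockout = rng.random() < cfg.pseudogene_fraction
        parts = make_kzfp_gene(
            rng, n_fingers, degenerate_positions=degenerate,
            knockout_start=knockout,
        )
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append((f"Zfp9{i + 101:03d}", parts, strand))

    # --- assign TE copies to chromosomes ---------------------------------
    chroms = list(cfg.chrom_lengths)
    weights = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    te_assign: dict[str, list[tuple[TEFamilySpec, int]]] = {c: [] for c in chroms}
    copy_counter = 0
    for fam in cfg.te_families:
        for _ in range(fam.copy_number):
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            copy_counter += 1
            te_assign[chrom].append((fam, copy_counter))

    # --- lay out each chromosome -----------------------------------------
    sequences: dict[str, str] = {}
    models: list[GeneModel] = []
    truth = GroundTruth()

    def _split(budget: int, m: int, min_sub: int = 10) -> list[int]:
        """Split a filler budget into m parts of at least min_sub bases."""
        if m == 1:
            return [budget]
        if budget < m * min_sub:
            raise LayoutError("gap too small for the TE copies placed in it")
        extra = rng.multinomial(budget - m * min_sub, np.full(m, 1.0 / m))
        return [int(x) + min_sub for x in extra]

    def _te_piece(payload: tuple) -> tuple[str, tuple, str]:
        fam, idx = payload
        d = _draw_divergence(rng, fam)
        n_subs = int(rng.poisson(fam.consensus_length * d / 100.0))
        seq, realized = _mutate(consensus[fam.name], rng, n_subs)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            seq = _revcomp(seq)
        div = 100.0 * realized / fam.consensus_length
        return ("te", (fam, idx, strand, div), seq)

    for chrom in chroms:
        length = cfg.chrom_lengths[chrom]
        pieces: list[tuple[str, object, str]] = []
        gaps: list[int] = []
        if chrom == cfg.cluster_chromosome:
            # a compact gene cluster between the anchors, with large
            # gene-free flanks outside; TE copies fall into gaps and
            # flanks in proportion to their lengths
            n = cfg.n_kzfp_genes
            lo_gap, hi_gap = cfg.gene_gap_range
            gene_gaps = [int(x) for x in rng.integers(lo_gap, hi_gap + 1, size=n + 1)]
            feature_bp = sum(len(a[1]) for a in anchors) + sum(
                len(g[1].dna) for g in genes
            )
            te_bp = sum(f.consensus_length for f, _ in te_assign[chrom])
            rem = length - feature_bp - te_bp - sum(gene_gaps)
            if rem < 2 * cfg.min_gap:
                raise LayoutError(
                    f"{chrom}: features exceed chromosome length {length}"
                )
            budgets = [rem // 2, *gene_gaps, rem - rem // 2]
            weights = np.asarray(budgets, dtype=float)
            weights /= weights.sum()
            slots: list[list] = [[] for _ in budgets]
            for payload in te_assign[chrom]:
                slots[int(rng.choice(len(slots), p=weights))].append(payload)
            # slot 0: left flank; 1..n+1: gene gaps; n+2: right flank
            slot_pieces: list[list] = []
            for payload_list in slots:
                slot_pieces.append([_te_piece(p) for p in payload_list])
            anchor_piece = [
                ("anchor", (anchors[i][0], anchors[i][2]), anchors[i][1])
                for i in range(2)
            ]
            gene_pieces = []
            for gi, (gid, parts, strand) in enumerate(genes):
                dna = parts.dna if strand == "+" else _revcomp(parts.dna)
                gene_pieces.append(("gene", gi, dna))
            order = [None, anchor_piece[0]]
            for gi in range(n):
                order.extend([None, gene_pieces[gi]])
            order.extend([None, anchor_piece[1], None])
            # interleave: for each slot emit its filler splits around TEs
            slot_iter = iter(range(len(budgets)))
            for element in order:
                if element is None:
                    si = next(slot_iter)
                    parts = _split(budgets[si], len(slot_pieces[si]) + 1)
                    for piece, gap in zip(slot_pieces[si], parts[:-1]):
                        gaps.append(gap)
                        pieces.append(piece)
                    gaps.append(parts[-1])
                else:
                    pieces.append(element)
            # trailing structure: gaps has len(pieces)+1 entries by design
            assert len(gaps) == len(pieces) + 1
            # merge boundary gaps is unnecessary: emission interleaves below
            gaps_arr = gaps
        else:
            tes = list(te_assign[chrom])
            rng.shuffle(tes)
            pieces = [_te_piece(p) for p in tes]
            feature_bp = sum(len(p[2]) for p in pieces)
            n_gaps = len(pieces) + 1
            filler = length - feature_bp - n_gaps * cfg.min_gap
            if filler < 0:
                raise LayoutError(
                    f"{chrom}: features ({feature_bp} bp) exceed chromosome "
                    f"length {length}"
                )
            extra = rng.multinomial(filler, np.full(n_gaps, 1.0 / n_gaps))
            gaps_arr = [int(x) + cfg.min_gap for x in extra]
        gaps = gaps_arr

        seq_parts: list[str] = []
        pos = 0
        for i, (kind, payload, dna) in enumerate(pieces):
            g = int(gaps[i])
            seq_parts.append(_random_dna(rng, g))
            pos += g
            if kind == "anchor":
                name, model = payload
                placed = _place_model(
                    model, f"{name}", chrom, pos, "+", len(dna),
                    attrs={"Name": name},
                )
                placed.gene_class = "non-kzfp"
                models.append(placed)
                truth.genes.append(
                    GeneRecord(name, chrom, pos, pos + len(dna), "+",
                               "non-kzfp", "")
                )
            elif kind == "gene":
                gid, parts, strand = genes[payload]
                placed = _place_model(
                    parts.model, gid, chrom, pos, strand, len(dna),
                    attrs={"Name": gid},
                )
                cls = "pseudogene" if parts.dna[30:33] != "ATG" else "coding"
                placed.gene_class = cls
                models.append(placed)
                truth.genes.append(
                    GeneRecord(gid, chrom, pos, pos + len(dna), strand, cls,
                               "".join(parts.fingerprints))
                )
            else:
                fam, idx, strand, div = payload
                truth.te_copies.append(
                    TECopyRecord(
                        f"{idx}", fam.name, chrom, pos, pos + len(dna),
                        strand, div,
                    )
                )
            seq_parts.append(dna)
            pos += len(dna)
        seq_parts.append(_random_dna(rng, int(gaps[-1])))
        sequences[chrom] = "".join(seq_parts)
        assert len(sequences[chrom]) == length

    locus = locate_cluster(models, *cfg.anchor_gene_names)
    sim = SyntheticGenome(
        config=cfg, sequences=sequences, models=models, truth=truth,
        consensus=consensus, locus=locus,
    )

    for k, ev in enumerate(cfg.duplication_events):
        block = block_interval_for_genes(sim, ev.first_gene, ev.last_gene)
        reserved = [
            block_interval_for_genes(sim, e.first_gene, e.last_gene)
            for e in cfg.duplication_events[k + 1 :]
        ]
        apply_segmental_duplication(
            sim, block, ev.rounds, ev.post_rate, rng, reserved=reserved
        )
    truth.validate()
    return sim


def block_interval_for_genes(
    sim: SyntheticGenome, first_gene: int, last_gene: int, pad: int = 50
) -> tuple[int, int]:
    """Genomic interval covering planted KZFP genes first..last (inclusive
    indices, cluster order) plus a small pad into the flanking gaps."""
    planted = [g for g in sim.truth.genes
               if g.origin == "planted" and g.gene_class != "non-kzfp"]
    planted.sort(key=lambda g: g.start)
    if not (0 <= first_gene <= last_gene < len(planted)):
        raise ValueError("gene index range outside the planted gene list")
    return planted[first_gene].start - pad, planted[last_gene].end + pad


def te_bearing_block(
    sim: SyntheticGenome, family: str, width: int = 4
) -> tuple[int, int]:
    """Gene index range (inclusive) of ``width`` consecutive planted genes
    whose span carries the most copies of ``family`` — the natural substrate
    for a TE-co-duplicating segmental duplication."""
    planted = [g for g in sim.truth.genes
               if g.origin == "planted" and g.gene_class != "non-kzfp"]
    planted.sort(key=lambda g: g.start)
    if len(planted) < width:
        raise ValueError("fewer planted genes than the requested block width")
    best, best_count = 0, -1
    for i in range(len(planted) - width + 1):
        span = (planted[i].start, planted[i + width - 1].end)
        count = sum(
            1 for t in sim.truth.te_copies
            if t.chromosome == sim.locus.chromosome
            and t.family == family
            and span[0] <= t.start and t.end <= span[1]
        )
        if count > best_count:
            best, best_count = i, count
    return best, best + width - 1


def apply_segmental_duplication(
    sim: SyntheticGenome,
    block: tuple[int, int],
    rounds: int,
    post_rate: float,
    rng: np.random.Generator,
    reserved: list[tuple[int, int]] | None = None,
) -> SyntheticGenome:
    """Duplicate a cluster block ``rounds`` times.

    Each round copies the *source* block sequence, mutates the copy at
    ``post_rate`` substitutions per base, and inserts it at a uniformly
    chosen position in a feature-free gap of the cluster locus.  Genes and
    TE copies inside the block are registered as duplicates with parent
    links; duplicate gene class and fingerprint are re-derived from the
    final sequence, duplicate TE divergence is recomputed against the
    family consensus.  The cluster grows by ``rounds`` x block length.
    """
    from .genes import classify_transcript, fingerprint_array

    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    chrom = sim.locus.chromosome
    b0, b1 = block
    if b0 < sim.locus.start0 or b1 > sim.locus.end0:
        raise ValueError("block is not inside the cluster locus")
    anchors = set(sim.config.anchor_gene_names)
    for m in sim.models:
        if m.attributes.get("Name", m.id) in anchors and m.chromosome == chrom:
            if m.start < b1 and m.end > b0:
                raise ValueError("block overlaps an anchor gene")

    sim._n_blocks += 1
    block_id = f"block{sim._n_blocks}"
    src_genes = [
        g for g in sim.truth.genes
        if g.chromosome == chrom and b0 <= g.start and g.end <= b1
    ]
    src_tes = [
        t for t in sim.truth.te_copies
        if t.chromosome == chrom and b0 <= t.start and t.end <= b1
    ]
    for g in src_genes:
        if g.block_id is None:
            g.block_id = block_id
    src_models = {m.id: m for m in sim.models if m.id in {g.id for g in src_genes}}

    copies: list[tuple[int, int]] = []
    dup_gene_ids: list[str] = []
    dup_te_ids: list[str] = []
    for rnd in range(1, rounds + 1):
        L = b1 - b0
        mutated = _mutate_rate(sim.sequences[chrom][b0:b1], rng, post_rate)
        # Keep insertions at least one gene-gap away from any duplication
        # interval so independent blocks never become adjacent in gene
        # order (which would merge their label patterns).
        margin = sim.config.gene_gap_range[1] + 2_000
        gaps = _locus_gaps(
            sim, exclude=[(b0, b1), *copies, *(reserved or [])],
            margin=margin,
        )
        if not gaps:
            gaps = _locus_gaps(
                sim, exclude=[(b0, b1), *copies, *(reserved or [])]
            )
        if not gaps:
            raise LayoutError("no feature-free gap available for insertion")
        gs, ge = gaps[int(rng.integers(0, len(gaps)))]
        p = int(rng.integers(gs, ge))
        delta = p - b0

        # Duplicate records are laid out in the post-insertion frame (the
        # copy occupies [p, p+L) once everything >= p shifts right), so
        # build them now and append them only after the shift.
        dup_genes, dup_models, dup_tes = [], [], []
        for g in src_genes:
            dup = GeneRecord(
                id=f"{g.id}_{block_id}r{rnd}",
                chromosome=chrom,
                start=g.start + delta,
                end=g.end + delta,
                strand=g.strand,
                gene_class=g.gene_class,       # refined below
                fingerprint_key="",            # refined below
                block_id=block_id,
                origin="duplication",
                parent=g.id,
            )
            dup_genes.append(dup)
            dup_gene_ids.append(dup.id)
            model = src_models[g.id]
            dup_models.append(
                GeneModel(
                    id=dup.id,
                    chromosome=chrom,
                    strand=model.strand,
                    exons=[(s + delta, e + delta) for s, e in model.exons],
                    cds=[(s + delta, e + delta) for s, e in model.cds]
                    if model.cds else None,
                    attributes={"Name": dup.id},
                )
            )
        for t in src_tes:
            dup = TECopyRecord(
                id=f"{t.id}_{block_id}r{rnd}",
                family=t.family,
                chromosome=chrom,
                start=t.start + delta,
                end=t.end + delta,
                strand=t.strand,
                percent_divergence=t.percent_divergence,  # refined below
                origin="duplication",
                parent=t.id,
            )
            dup_tes.append(dup)
            dup_te_ids.append(dup.id)

        sim.sequences[chrom] = (
            sim.sequences[chrom][:p] + mutated + sim.sequences[chrom][p:]
        )
        sim._shift(chrom, p, L)
        if p <= b0:
            b0, b1 = b0 + L, b1 + L
        copies = [
            (s + L, e + L) if s >= p else (s, e) for s, e in copies
        ]
        copies.append((p, p + L))
        reserved = [
            (s + L, e + L) if s >= p else (s, e) for s, e in (reserved or [])
        ]
        sim.truth.genes.extend(dup_genes)
        sim.truth.te_copies.extend(dup_tes)
        sim.models.extend(dup_models)

    sim.truth.blocks.append(
        BlockRecord(block_id, chrom, (b0, b1), copies, [g.id for g in src_genes])
    )

    # refine duplicate gene class/fingerprint and TE divergence from the
    # final sequence
    genome = sim.sequences
    dup_gene_set = set(dup_gene_ids)
    rec_by_id = {g.id: g for g in sim.truth.genes}
    for m in sim.models:
        if m.id in dup_gene_set:
            rec = rec_by_id[m.id]
            rec.gene_class = classify_transcript(m, genome)
            rec.fingerprint_key = fingerprint_array(m, genome).key
            m.gene_class = rec.gene_class
    dup_te_set = set(dup_te_ids)
    for t in sim.truth.te_copies:
        if t.id in dup_te_set:
            seq = sim.sequences[chrom][t.start : t.end]
            fwd = seq if t.strand == "+" else _revcomp(seq)
            cons = sim.consensus[t.family]
            mism = sum(a != b for a, b in zip(fwd, cons))
            t.percent_divergence = 100.0 * mism / len(cons)
    return sim


def _locus_gaps(
    sim: SyntheticGenome,
    exclude: list[tuple[int, int]],
    min_len: int = 20,
    margin: int = 0,
) -> list[tuple[int, int]]:
    chrom = sim.locus.chromosome
    covered = [(s - margin, e + margin) for s, e in exclude]
    # never insert inside an earlier duplication's source or copies: keeps
    # every planted block contiguous in gene order
    for b in sim.truth.blocks:
        if b.chromosome == chrom:
            covered.append((b.source[0] - margin, b.source[1] + margin))
            covered.extend((s - margin, e + margin) for s, e in b.copies)
    for g in sim.truth.genes:
        if g.chromosome == chrom:
            covered.append((g.start, g.end))
    for t in sim.truth.te_copies:
        if t.chromosome == chrom:
            covered.append((t.start, t.end))
    covered = sorted(
        (max(s, sim.locus.start0), min(e, sim.locus.end0))
        for s, e in covered
        if s < sim.locus.end0 and e > sim.locus.start0
    )
    gaps = []
    cursor = sim.locus.start0
    for s, e in covered:
        if s - cursor >= min_len:
            gaps.append((cursor, s))
        cursor = max(cursor, e)
    if sim.locus.end0 - cursor >= min_len:
        gaps.append((cursor, sim.locus.end0))
    return gaps


# ---------------------------------------------------------------------------
# fragmentation into contigs
# ---------------------------------------------------------------------------

@dataclass
class ContigSet:
    sequences: dict[str, str]
    paf: list[PafRecord]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.sequences, outdir / "contigs.fa")
        write_paf(self.paf, outdir / "alignments.paf")


def fragment_into_contigs(
    sim: SyntheticGenome,
    rng: np.random.Generator | None = None,
) -> ContigSet:
    """Cut the genome into contigs and emit exact-bookkeeping PAF records.

    Breakpoints are uniform over the genome; each contig is
    reverse-complemented with the configured flip probability (PAF strand
    '-'); nested extras are proper sub-intervals of existing contigs.
    Contig provenance is appended to the ground truth.
    """
    cfg = sim.config.fragmentation
    if rng is None:
        rng = np.random.default_rng(sim.config.seed + 7_654_321)
    chroms = list(sim.sequences)
    lengths = np.array([len(sim.sequences[c]) for c in chroms], dtype=float)
    weights = lengths / lengths.sum()

    breaks: dict[str, set[int]] = {c: set() for c in chroms}
    for _ in range(cfg.n_breakpoints):
        c = chroms[int(rng.choice(len(chroms), p=weights))]
        L = len(sim.sequences[c])
        if L > 1:
            breaks[c].add(int(rng.integers(1, L)))

    contigs: dict[str, str] = {}
    paf: list[PafRecord] = []
    records: list[ContigRecord] = []
    idx = 0
    for c in chroms:
        L = len(sim.sequences[c])
        cuts = [0] + sorted(breaks[c]) + [L]
        for s, e in zip(cuts, cuts[1:]):
            idx += 1
            name = f"contig_{idx:04d}"
            flipped = rng.random() < cfg.flip_probability
            seq = sim.sequences[c][s:e]
            contigs[name] = _revcomp(seq) if flipped else seq
            strand = "-" if flipped else "+"
            paf.append(
                PafRecord(name, e - s, 0, e - s, strand, c, L, s, e,
                          e - s, e - s, 60)
            )
            records.append(ContigRecord(name, c, s, e, strand))

    base = list(records)
    for _ in range(cfg.n_nested_extras):
        parents = [r for r in base if r.end - r.start >= 300]
        if not parents:
            break
        parent = parents[int(rng.integers(0, len(parents)))]
        span = parent.end - parent.start
        a = int(rng.integers(1, span - 150))
        b = a + int(rng.integers(100, min(span - a, span - 1)))
        s, e = parent.start + a, parent.start + b
        idx += 1
        name = f"contig_{idx:04d}"
        flipped = rng.random() < cfg.flip_probability
        seq = sim.sequences[parent.chromosome][s:e]
        contigs[name] = _revcomp(seq) if flipped else seq
        strand = "-" if flipped else "+"
        L = len(sim.sequences[parent.chromosome])
        paf.append(
            PafRecord(name, e - s, 0, e - s, strand, parent.chromosome, L,
                      s, e, e - s, e - s, 60)
        )
        records.append(
            ContigRecord(name, parent.chromosome, s, e, strand,
                         nested_in=parent.name)
        )

    sim.truth.contigs.extend(records)
    return ContigSet(contigs, paf)
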