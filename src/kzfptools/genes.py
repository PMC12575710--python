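"""Gene models, GFF3 I/O, and KZFP transcript classification.

Transcripts are classified with an automated stand-in for manual curation:

* ``coding`` — some ORF (first ATG per frame) encodes both a KRAB domain
  and at least one zinc finger;
* ``other`` — the start codon is intact and a ZF-bearing ORF of at least
  100 codons exists, but without a KRAB domain (residual coding potential);
* ``pseudogene`` — a zinc-finger array is present in some frame but the
  KRAB domain or the start codon is missing;
* ``non-kzfp`` — no zinc-finger array at all.

"Start codon intact" is operationalised as: the first ATG of the spliced
transcript occurs within its first 90 nt, i.e. the encoded protein is not
grossly N-terminally truncated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq

from .fingers import FingerprintArray, ZincFinger, detect_krab, scan_c2h2

__all__ = [
    "GeneModel",
    "read_gff3",
    "write_gff3",
    "spliced_sequence",
    "classify_transcript",
    "find_zf_exon",
    "fingerprint_array",
    "annotate_genes",
]

CLASSES = ("coding", "pseudogene", "other", "non-kzfp")

#: nt window at the transcript 5' end within which the first ATG must fall
#: for the start codon to count as intact.
START_WINDOW_NT = 90

#: minimum ORF length (codons) for the residual-coding-potential class.
MIN_OTHER_ORF_CODONS = 100


@dataclass
class GeneModel:
    """One transcript model. Coordinates are 0-based half-open, genomic.

    ``exons`` are ordered 5'->3' (decreasing genomic coordinate on the
    minus strand).  ``gene_class`` is filled by :func:`classify_transcript`
    or carried from a ``kzfp_class`` GFF3 attribute.
    """

    id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] | None = None
    gene_class: str | None = None
    zf_exon_index: int | None = None
    attributes: dict = field(default_factory=dict)

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end

    def __post_init__(self) -> None:
        order = sorted(self.exons)
        if self.strand == "-":
            order = order[::-1]
        if self.exons != order:
            self.exons = order
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if e1 > s2:
                raise ValueError(f"overlapping exons in gene {self.id}")


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def spliced_sequence(model: GeneModel, genome: dict[str, str]) -> str:
    """Spliced transcript sequence, 5'->3'."""
    chrom = genome[model.chromosome]
    for s, e in model.exons:
        if s < 0 or e > len(chrom):
            raise ValueError(
                f"exon {s}-{e} of {model.id} outside chromosome "
                f"{model.chromosome} (length {len(chrom)})"
            )
    parts = [chrom[s:e] for s, e in sorted(model.exons)]
    seq = "".join(parts)
    return _revcomp(seq) if model.strand == "-" else seq


def _translate(seq: str) -> str:
    n = len(seq) - len(seq) % 3
    return str(Seq(seq[:n]).translate())


def _orfs(spliced: str) -> list[tuple[int, str]]:
    """(ATG position in nt, ORF peptide) for each of the three frames,
    taking the first ATG of each frame."""
    out = []
    for f in range(3):
        prot = _translate(spliced[f:])
        i = prot.find("M")
        if i < 0:
            continue
        stop = prot.find("*", i)
        pep = prot[i:] if stop < 0 else prot[i:stop]
        out.append((f + 3 * i, pep))
    return out


def classify_transcript(model: GeneModel, genome: dict[str, str]) -> str:
    """Classify a transcript as coding / other / pseudogene / non-kzfp."""
    spliced = spliced_sequence(model, genome).upper()
    has_zf = any(scan_c2h2(_translate(spliced[f:])) for f in range(3))
    orfs = _orfs(spliced)
    for _, orf in orfs:
        if scan_c2h2(orf) and detect_krab(orf)[0]:
            return "coding"
    if not has_zf:
        return "non-kzfp"
    for atg, orf in orfs:
        # residual coding potential: the ORF's own start codon must sit
        # near the transcript 5' end and the ORF must be substantial
        if (
            atg < START_WINDOW_NT
            and len(orf) >= MIN_OTHER_ORF_CODONS
            and scan_c2h2(orf)
            and not detect_krab(orf)[0]
        ):
            return "other"
    return "pseudogene"


def _best_frame_fingers(spliced: str) -> tuple[int, list[ZincFinger]]:
    """Frame (0-2) whose full translation carries the most fingers."""
    best_f, best = 0, []
    for f in range(3):
        fingers = scan_c2h2(_translate(spliced[f:]))
        if len(fingers) > len(best):
            best_f, best = f, fingers
    return best_f, best


def find_zf_exon(model: GeneModel, genome: dict[str, str]) -> int | None:
    """Index (into ``model.exons``, 5'->3') of the zinc-finger-array exon.

    Fingers found in the best-frame translation of the spliced transcript
    are mapped back to exons through transcript coordinates; the exon
    holding the majority of fingers wins, ties going 3'-most.  ``None`` if
    the transcript carries no finger.
    """
    spliced = spliced_sequence(model, genome)
    frame, fingers = _best_frame_fingers(spliced)
    if not fingers:
        return None
    # cumulative transcript offsets of the 5'->3' exon list
    bounds = []
    off = 0
    for s, e in model.exons:
        bounds.append((off, off + (e - s)))
        off += e - s
    counts = [0] * len(model.exons)
    for zf in fingers:
        mid_aa = (zf.protein_start + zf.protein_end) // 2
        nt = frame + 3 * mid_aa
        for i, (lo, hi) in enumerate(bounds):
            if lo <= nt < hi:
                counts[i] += 1
                break
    best = max(range(len(counts)), key=lambda i: (counts[i], i))
    return best if counts[best] else None


def fingerprint_array(model: GeneModel, genome: dict[str, str]) -> FingerprintArray:
    """Fingerprint array of a transcript.

    Prefers the coding ORF (KRAB + fingers) when one exists, otherwise the
    frame translation carrying the most fingers, so truncated pseudogene
    arrays are still reported.
    """
    spliced = spliced_sequence(model, genome).upper()
    for _, orf in _orfs(spliced):
        fingers = scan_c2h2(orf)
        if fingers and detect_krab(orf)[0]:
            return FingerprintArray.from_fingers(fingers)
    _, fingers = _best_frame_fingers(spliced)
    return FingerprintArray.from_fingers(fingers)


def annotate_genes(
    models: list[GeneModel], genome: dict[str, str]
) -> pd.DataFrame:
    """Per-transcript annotation table (the ``annotate`` CLI output).

    Columns: gene id, chromosome, start/end (1-based inclusive), strand,
    class, number of fingers, fingerprint array identity key, display
    string with flags, and the zinc-finger exon index.
    """
    rows = []
    for m in models:
        cls = classify_transcript(m, genome)
        m.gene_class = cls
        arr = fingerprint_array(m, genome)
        zf_exon = find_zf_exon(m, genome)
        m.zf_exon_index = zf_exon
        rows.append(
            {
                "gene_id": m.id,
                "chromosome": m.chromosome,
                "start": m.start + 1,
                "end": m.end,
                "strand": m.strand,
                "class": cls,
                "n_fingers": len(arr),
                "fingerprint_array": arr.key,
                "fingerprint_display": arr.display,
                "zf_exon_index": zf_exon,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GFF3 I/O (gene -> mRNA -> exon/CDS, with a kzfp_class attribute)
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models from a GFF3 file (one model per mRNA feature).

    Honors multi-exon mRNA features; a ``kzfp_class`` attribute on the gene
    or mRNA is carried into :attr:`GeneModel.gene_class`.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for mrna in db.features_of_type("mRNA", order_by="start"):
        gene_id = mrna.attributes.get("Parent", [mrna.id])[0]
        attrs = {k: v[0] for k, v in mrna.attributes.items() if v}
        try:
            gene = db[gene_id]
            for k, v in gene.attributes.items():
                if v:
                    attrs.setdefault(k, v[0])
        except gffutils.FeatureNotFoundError:
            pass
        exons = [
            (f.start - 1, f.end)
            for f in db.children(mrna, featuretype="exon", order_by="start")
        ]
        cds = [
            (f.start - 1, f.end)
            for f in db.children(mrna, featuretype="CDS", order_by="start")
        ]
        models.append(
            GeneModel(
                id=gene_id,
                chromosome=mrna.seqid,
                strand=mrna.strand,
                exons=exons or [(mrna.start - 1, mrna.end)],
                cds=cds or None,
                gene_class=attrs.get("kzfp_class"),
                attributes=attrs,
            )
        )
    return models


def write_gff3(models: list[GeneModel], path: str | Path) -> None:
    """Emit gene/mRNA/exon/CDS features, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            cls = f";kzfp_class={m.gene_class}" if m.gene_class else ""
            name = m.attributes.get("Name", m.id)
            fh.write(
                f"{m.chromosome}\tkzfptools\tgene\t{m.start + 1}\t{m.end}\t.\t"
                f"{m.strand}\t.\tID={m.id};Name={name}{cls}\n"
            )
            tid = f"{m.id}.t1"
            fh.write(
                f"{m.chromosome}\tkzfptools\tmRNA\t{m.start + 1}\t{m.end}\t.\t"
                f"{m.strand}\t.\tID={tid};Parent={m.id}\n"
            )
            for i, (s, e) in enumerate(sorted(m.exons), 1):
                fh.write(
                    f"{m.chromosome}\tkzfptools\texon\t{s + 1}\t{e}\t.\t"
                    f"{m.strand}\t.\tID={tid}.exon{i};Parent={tid}\n"
                )
            for i, (s, e) in enumerate(sorted(m.cds or []), 1):
                fh.write(
                    f"{m.chromosome}\tkzfptools\tCDS\t{s + 1}\t{e}\t.\t"
                    f"{m.strand}\t0\tID={tid}.cds{i};Parent={tid}\n"
                )
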