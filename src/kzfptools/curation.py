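"""Contig curation from PAF alignments against a reference.

The procedure mirrors how a de novo assembly is tidied against a
reference without scaffolding: (i) contigs aligning only to unknown
targets are dropped; (ii) a contig aligning to several chromosomes is
assigned to the chromosome carrying its single longest alignment block
(ties: larger total aligned bp, then lexicographic name); (iii) contigs
whose merged reference span is fully nested inside a retained contig's
span are dropped; finally contigs whose aligned bases lie mostly on the
minus strand are reverse-complemented, and output is ordered by
(chromosome, reference span start).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "PafRecord",
    "read_paf",
    "write_paf",
    "CurationDecision",
    "assign_chromosome",
    "resolve_nesting",
    "orient_and_emit",
    "curate",
]


@dataclass
class PafRecord:
    """One PAF alignment block; 0-based half-open on both sides."""

    query_name: str
    query_length: int
    query_start: int
    query_end: int
    strand: str
    target_name: str
    target_length: int
    target_start: int
    target_end: int
    matches: int
    block_length: int
    mapq: int = 255

    def __post_init__(self) -> None:
        for s, e, ln, side in (
            (self.query_start, self.query_end, self.query_length, "query"),
            (self.target_start, self.target_end, self.target_length, "target"),
        ):
            if not (0 <= s < e <= ln):
                raise ValueError(
                    f"{self.query_name}: invalid {side} interval {s}-{e}/{ln}"
                )
        if self.matches > self.block_length:
            raise ValueError(f"{self.query_name}: matches exceed block length")

    @property
    def target_span(self) -> int:
        return self.target_end - self.target_start


def read_paf(path: str | Path) -> list[PafRecord]:
    """Read PAF; the 12 mandatory columns are kept, optional tags dropped."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 12:
                raise ValueError(f"{path}: line {lineno}: expected >=12 columns")
            try:
                records.append(
                    PafRecord(
                        query_name=cols[0],
                        query_length=int(cols[1]),
                        query_start=int(cols[2]),
                        query_end=int(cols[3]),
                        strand=cols[4],
                        target_name=cols[5],
                        target_length=int(cols[6]),
                        target_start=int(cols[7]),
                        target_end=int(cols[8]),
                        matches=int(cols[9]),
                        block_length=int(cols[10]),
                        mapq=int(cols[11]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return records


def write_paf(records: list[PafRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.query_name}\t{r.query_length}\t{r.query_start}\t"
                f"{r.query_end}\t{r.strand}\t{r.target_name}\t"
                f"{r.target_length}\t{r.target_start}\t{r.target_end}\t"
                f"{r.matches}\t{r.block_length}\t{r.mapq}\n"
            )


@dataclass
class CurationDecision:
    contig: str
    verdict: str  # keep | drop-unplaced | drop-nested
    chromosome: str | None = None
    flipped: bool = False
    longest_bp: int = 0
    total_bp: int = 0
    span: tuple[int, int] | None = None


def assign_chromosome(
    records: list[PafRecord], known_chromosomes: set[str]
) -> tuple[str | None, dict]:
    """Assign one contig to the chromosome of its longest alignment block.

    Alignments to targets outside ``known_chromosomes`` are discarded; if
    none remain the contig is unplaced.  Ties on the longest block go to
    the chromosome with more total aligned bp, then lexicographic order.
    """
    usable = [r for r in records if r.target_name in known_chromosomes]
    if not usable:
        return None, {"longest_bp": 0, "total_bp": 0, "span": None}
    totals: dict[str, int] = {}
    longest: dict[str, int] = {}
    for r in usable:
        totals[r.target_name] = totals.get(r.target_name, 0) + r.target_span
        longest[r.target_name] = max(longest.get(r.target_name, 0), r.target_span)
    chrom = min(
        longest,
        key=lambda c: (-longest[c], -totals[c], c),
    )
    on = [r for r in usable if r.target_name == chrom]
    span = (min(r.target_start for r in on), max(r.target_end for r in on))
    return chrom, {
        "longest_bp": longest[chrom],
        "total_bp": totals[chrom],
        "span": span,
    }


def resolve_nesting(
    contigs: dict[str, dict],
) -> set[str]:
    """Drop set of nested contigs on one chromosome.

    ``contigs`` maps contig id -> evidence dict with ``span`` (merged
    reference span) and ``longest_bp``.  Contigs are processed in
    decreasing longest-alignment order; one is dropped iff its span is
    fully contained in an already-retained contig's span and its longest
    alignment is strictly smaller.  Partially overlapping contigs are all
    retained.
    """
    order = sorted(
        contigs, key=lambda c: (-contigs[c]["longest_bp"], c)
    )
    retained: list[str] = []
    dropped: set[str] = set()
    for cid in order:
        s, e = contigs[cid]["span"]
        nested = False
        for rid in retained:
            rs, re_ = contigs[rid]["span"]
            if (
                rs <= s
                and e <= re_
                and contigs[cid]["longest_bp"] < contigs[rid]["longest_bp"]
            ):
                nested = True
                break
        if nested:
            dropped.add(cid)
        else:
            retained.append(cid)
    return dropped


def _majority_minus(records: list[PafRecord], chrom: str) -> bool:
    minus = sum(r.target_span for r in records if r.target_name == chrom and r.strand == "-")
    plus = sum(r.target_span for r in records if r.target_name == chrom and r.strand == "+")
    return minus > plus


def curate(
    paf: list[PafRecord],
    known_chromosomes: set[str],
) -> list[CurationDecision]:
    """Full decision pass: assignment, nesting, strand, ordering."""
    by_contig: dict[str, list[PafRecord]] = {}
    for r in paf:
        by_contig.setdefault(r.query_name, []).append(r)
    decisions: dict[str, CurationDecision] = {}
    per_chrom: dict[str, dict[str, dict]] = {}
    for cid, recs in by_contig.items():
        chrom, ev = assign_chromosome(recs, known_chromosomes)
        if chrom is None:
            decisions[cid] = CurationDecision(cid, "drop-unplaced")
            continue
        decisions[cid] = CurationDecision(
            cid,
            "keep",
            chromosome=chrom,
            flipped=_majority_minus(recs, chrom),
            longest_bp=ev["longest_bp"],
            total_bp=ev["total_bp"],
            span=ev["span"],
        )
        per_chrom.setdefault(chrom, {})[cid] = ev
    for chrom, group in per_chrom.items():
        for cid in resolve_nesting(group):
            decisions[cid].verdict = "drop-nested"
    # report in input order
    return [decisions[cid] for cid in by_contig]


def orient_and_emit(
    sequences: dict[str, str],
    decisions: list[CurationDecision],
) -> tuple[dict[str, str], pd.DataFrame]:
    """Apply strand corrections and order the curated assembly.

    Returns the curated sequences (insertion order = (assigned chromosome,
    reference span start)) and a per-contig report.  A kept contig with no
    sequence is an error.
    """
    kept = [d for d in decisions if d.verdict == "keep"]
    for d in kept:
        if d.contig not in sequences:
            raise ValueError(f"no sequence for kept contig {d.contig}")
    kept.sort(key=lambda d: (d.chromosome, d.span[0]))
    curated: dict[str, str] = {}
    for d in kept:
        seq = sequences[d.contig]
        curated[d.contig] = (
            str(Seq(seq).reverse_complement()) if d.flipped else seq
        )
    report = pd.DataFrame(
        [
            {
                "contig": d.contig,
                "verdict": d.verdict,
                "chromosome": d.chromosome or "",
                "flipped": d.flipped,
                "longest_bp": d.longest_bp,
                "total_bp": d.total_bp,
                "span_start": d.span[0] if d.span else -1,
                "span_end": d.span[1] if d.span else -1,
            }
            for d in decisions
        ]
    )
    return curated, report
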