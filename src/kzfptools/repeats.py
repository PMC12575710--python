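"""RepeatMasker annotations and TE enrichment statistics.

The enrichment of a TE family in a cluster locus is
``log2[(bp of TE in locus / bp of locus) / (bp of TE genome-wide / bp of
genome)]``, with annotated bases counted as the union of family intervals
(clipped at the locus boundary).  Significance comes from a permutation
null in which every region is independently re-placed uniformly on its own
chromosome, length preserved, overlaps permitted; the empirical p-value
uses the (1+k)/(n+1) correction and a Z-score is reported alongside.

A *copy* of a repeat is the set of .out rows sharing a RepeatMasker join
ID (fragments of one interrupted insertion); representation statistics
count copies, while enrichment counts bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import ClusterLocus

__all__ = [
    "RepeatRecord",
    "read_repeatmasker_out",
    "write_repeatmasker_out",
    "PermutationConfig",
    "PermutationResult",
    "EnrichmentResult",
    "enrichment",
    "enrichment_table",
    "permutation_overlap_test",
    "family_representation",
    "select_display_families",
    "DivergenceGroup",
    "duplication_signature",
    "grouped_fraction",
    "duplication_contrast",
]

ABSENT_SENTINEL = "NA_absent"


@dataclass
class RepeatRecord:
    """One RepeatMasker .out row; ``begin``/``end`` 1-based inclusive."""

    chromosome: str
    begin: int
    end: int
    strand: str
    family: str
    class_family: str
    percent_divergence: float
    join_id: str
    score: int = 0

    def __post_init__(self) -> None:
        if self.begin > self.end:
            raise ValueError(f"repeat {self.family}: begin > end")
        if self.percent_divergence < 0:
            raise ValueError("negative divergence")

    @property
    def start0(self) -> int:
        return self.begin - 1

    @property
    def end0(self) -> int:
        return self.end

    @property
    def length(self) -> int:
        return self.end - self.begin + 1


def read_repeatmasker_out(path: str | Path) -> list[RepeatRecord]:
    """Parse a standard RepeatMasker .out file (3 header lines).

    Strand ``C`` maps to ``-``; a trailing asterisk overlap flag is
    tolerated.  Malformed rows raise with their line number.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if lineno <= 3:
                continue  # SW/score header block
            if not line.strip():
                continue
            cols = line.split()
            if len(cols) < 15:
                raise ValueError(f"{path}: line {lineno}: expected >=15 columns")
            try:
                records.append(
                    RepeatRecord(
                        chromosome=cols[4],
                        begin=int(cols[5]),
                        end=int(cols[6]),
                        strand="-" if cols[8] in ("C", "-") else "+",
                        family=cols[9],
                        class_family=cols[10],
                        percent_divergence=float(cols[1]),
                        join_id=cols[14],
                        score=int(float(cols[0])),
                    )
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return records


_OUT_HEADER = (
    "   SW   perc perc perc  query     position in query     matching"
    "  repeat        position in repeat\n"
    "score   div. del. ins.  sequence  begin end    (left)   repeat"
    "        class/family  begin end (left)  ID\n"
    "\n"
)


def write_repeatmasker_out(
    records: list[RepeatRecord],
    path: str | Path,
    chrom_lengths: dict[str, int] | None = None,
    consensus_lengths: dict[str, int] | None = None,
) -> None:
    """Emit records in the standard 15-column .out layout."""
    chrom_lengths = chrom_lengths or {}
    consensus_lengths = consensus_lengths or {}
    with open(path, "w") as fh:
        fh.write(_OUT_HEADER)
        for r in records:
            left = chrom_lengths.get(r.chromosome)
            qleft = f"({left - r.end})" if left is not None else "(0)"
            clen = consensus_lengths.get(r.family, r.length)
            strand = "C" if r.strand == "-" else "+"
            fh.write(
                f"{r.score:>5} {r.percent_divergence:>6.1f}  0.0  0.0  "
                f"{r.chromosome}  {r.begin} {r.end} {qleft}  {strand}  "
                f"{r.family}  {r.class_family}  1 {clen} (0)  {r.join_id}\n"
            )


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def _union_bp(intervals: list[tuple[int, int]]) -> int:
    """Total covered bases of possibly-overlapping 0-based intervals."""
    total = 0
    last_end = None
    for s, e in sorted(intervals):
        if last_end is None or s >= last_end:
            total += e - s
            last_end = e
        elif e > last_end:
            total += e - last_end
            last_end = e
    return total


@dataclass
class EnrichmentResult:
    family: str
    cluster_bp: int
    genome_bp: int
    log2_enrichment: float | None  # None = family absent from the locus
    observed_overlap: int | None = None
    perm_mean: float | None = None
    perm_sd: float | None = None
    z: float | None = None
    p: float | None = None
    n_permutations: int | None = None


def enrichment(
    family: str,
    records: list[RepeatRecord],
    locus: ClusterLocus,
    genome_lengths: dict[str, int],
) -> EnrichmentResult:
    """Density-ratio enrichment of one family in the locus.

    Bases are counted as the union of the family's annotated intervals;
    overlap with the locus is clipped at its boundaries.  A family with no
    bases in the locus gets ``log2_enrichment=None`` (the "absent" grey
    tile); a family with no bases genome-wide is a caller error.
    """
    fam = [r for r in records if r.family == family]
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in fam:
        by_chrom.setdefault(r.chromosome, []).append((r.start0, r.end0))
    genome_bp = sum(_union_bp(iv) for iv in by_chrom.values())
    if genome_bp == 0:
        raise ValueError(f"family {family!r} has no annotated bases genome-wide")
    clipped = [
        (max(r.start0, locus.start0), min(r.end0, locus.end0))
        for r in fam
        if locus.overlaps(r.chromosome, r.start0, r.end0)
    ]
    cluster_bp = _union_bp(clipped)
    genome_total = sum(genome_lengths.values())
    if cluster_bp == 0:
        log2 = None
    else:
        log2 = float(
            np.log2((cluster_bp / locus.length) / (genome_bp / genome_total))
        )
    return EnrichmentResult(family, cluster_bp, genome_bp, log2)


def enrichment_table(
    records: list[RepeatRecord],
    locus: ClusterLocus,
    genome_lengths: dict[str, int],
    families: list[str] | None = None,
) -> pd.DataFrame:
    """Enrichment of every (or the given) families; skips families with no
    genome-wide bases and reports them in the ``skipped`` attribute."""
    fams = families or sorted({r.family for r in records})
    rows, skipped = [], []
    for fam in fams:
        try:
            res = enrichment(fam, records, locus, genome_lengths)
        except ValueError:
            skipped.append(fam)
            continue
        rows.append(
            {
                "family": fam,
                "cluster_bp": res.cluster_bp,
                "genome_bp": res.genome_bp,
                "log2_enrichment": (
                    ABSENT_SENTINEL
                    if res.log2_enrichment is None
                    else res.log2_enrichment
                ),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["skipped"] = skipped
    return df


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------

@dataclass
class PermutationConfig:
    """Uniform per-chromosome re-placement null (lengths preserved)."""

    n: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("need at least one permutation")


@dataclass
class PermutationResult:
    observed: int
    mean: float
    sd: float
    z: float
    p: float
    n: int


def _count_overlaps(
    starts: np.ndarray, lengths: np.ndarray, tstarts: np.ndarray, tends: np.ndarray
) -> np.ndarray:
    """Overlap indicator of regions (start matrix) against merged sorted
    disjoint target intervals on one chromosome."""
    ends = starts + lengths
    idx = np.searchsorted(tstarts, ends, side="left") - 1
    hit = idx >= 0
    safe = np.where(hit, idx, 0)
    return hit & (tends[safe] > starts)


def _merge(intervals: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    if not merged:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    arr = np.asarray(merged, dtype=np.int64)
    return arr[:, 0], arr[:, 1]


def permuted_overlap_counts(
    regions: list[tuple[str, int, int]],
    targets: dict[str, list[tuple[int, int]]],
    chrom_lengths: dict[str, int],
    n: int,
    rng: np.random.Generator,
) -> tuple[int, np.ndarray]:
    """Observed overlap count and ``n`` permuted counts.

    Regions and targets use 0-based half-open coordinates.  Each
    permutation independently redraws every region's start uniformly on
    its own chromosome; regions on chromosomes without targets contribute
    zero but are still validated against their chromosome length.
    """
    merged = {c: _merge(iv) for c, iv in targets.items()}
    observed = 0
    perm = np.zeros(n, dtype=np.int64)
    for chrom, s, e in regions:
        if e - s > chrom_lengths[chrom]:
            raise ValueError(
                f"region of length {e - s} exceeds chromosome {chrom}"
            )
        tstarts, tends = merged.get(chrom, (None, None))
        length = e - s
        max_start = chrom_lengths[chrom] - length
        starts = rng.integers(0, max_start + 1, size=n)
        if tstarts is None or len(tstarts) == 0:
            continue
        observed += int(
            _count_overlaps(
                np.asarray([s]), np.asarray([length]), tstarts, tends
            )[0]
        )
        perm += _count_overlaps(starts, np.full(n, length), tstarts, tends)
    return observed, perm


def permutation_overlap_test(
    regions: list[tuple[str, int, int]],
    locus: ClusterLocus,
    chrom_lengths: dict[str, int],
    cfg: PermutationConfig | None = None,
) -> PermutationResult:
    """Permutation test of region overlap with a cluster locus.

    ``observed`` counts regions overlapping the locus by >=1 bp;
    ``p = (1 + #{perm >= observed}) / (n + 1)``; ``Z`` is the usual
    standardised observed count (0 when the permutation spread is zero).
    """
    cfg = cfg or PermutationConfig()
    rng = np.random.default_rng(cfg.seed)
    targets = {locus.chromosome: [(locus.start0, locus.end0)]}
    observed, perm = permuted_overlap_counts(
        regions, targets, chrom_lengths, cfg.n, rng
    )
    return _summarise(observed, perm, cfg.n)


def _summarise(observed: int, perm: np.ndarray, n: int) -> PermutationResult:
    mean = float(perm.mean())
    sd = float(perm.std(ddof=1)) if n > 1 else 0.0
    z = 0.0 if sd == 0 else (observed - mean) / sd
    p = (1 + int((perm >= observed).sum())) / (n + 1)
    return PermutationResult(observed, mean, sd, z, p, n)


# ---------------------------------------------------------------------------
# copy-based representation
# ---------------------------------------------------------------------------

def _copies(records: list[RepeatRecord], family: str) -> dict[str, list[RepeatRecord]]:
    out: dict[str, list[RepeatRecord]] = {}
    for r in records:
        if r.family == family:
            out.setdefault(r.join_id, []).append(r)
    return out


def family_representation(
    family: str, records: list[RepeatRecord], locus: ClusterLocus
) -> float:
    """Fraction of a family's copies lying in the locus.

    Fragments sharing a join ID count as one copy; a copy is *in* when any
    of its fragments overlaps the locus by >=1 bp.
    """
    copies = _copies(records, family)
    if not copies:
        return 0.0
    inside = sum(
        any(locus.overlaps(r.chromosome, r.start0, r.end0) for r in frags)
        for frags in copies.values()
    )
    return inside / len(copies)


def select_display_families(
    records: list[RepeatRecord],
    locus: ClusterLocus,
    min_fraction: float = 0.02,
    min_in_locus: int = 10,
) -> list[str]:
    """Families with >2% of their copies and >10 copies inside the locus."""
    out = []
    for fam in sorted({r.family for r in records}):
        copies = _copies(records, fam)
        inside = sum(
            any(locus.overlaps(r.chromosome, r.start0, r.end0) for r in frags)
            for frags in copies.values()
        )
        if inside > min_in_locus and inside / len(copies) > min_fraction:
            out.append(fam)
    return out


# ---------------------------------------------------------------------------
# divergence grouping (segmental-duplication signature)
# ---------------------------------------------------------------------------

@dataclass
class DivergenceGroup:
    mean: float
    size: int
    values: list[float] = field(default_factory=list)


def duplication_signature(
    divergences: list[float],
    tolerance: float = 0.5,
    min_group: int = 3,
) -> list[DivergenceGroup]:
    """Groups of near-identical divergence values.

    Values are sorted; maximal runs whose consecutive gaps are all <=
    ``tolerance`` (percentage points) and whose size is >= ``min_group``
    are reported.  Co-duplicated TE copies share their parent's divergence
    and therefore pile up in such groups, unlike independent insertions.
    """
    vals = sorted(float(v) for v in divergences)
    if not all(np.isfinite(vals)):
        raise ValueError("divergences must be finite")
    groups: list[DivergenceGroup] = []
    run: list[float] = []
    for v in vals:
        if not run or v - run[-1] <= tolerance:
            run.append(v)
        else:
            if len(run) >= min_group:
                groups.append(DivergenceGroup(float(np.mean(run)), len(run), run))
            run = [v]
    if len(run) >= min_group:
        groups.append(DivergenceGroup(float(np.mean(run)), len(run), run))
    return groups


def grouped_fraction(
    divergences: list[float], tolerance: float = 0.5, min_group: int = 3
) -> float:
    """Fraction of values that fall inside some divergence group."""
    if not divergences:
        return 0.0
    groups = duplication_signature(divergences, tolerance, min_group)
    return sum(g.size for g in groups) / len(divergences)


def duplication_contrast(
    in_locus: list[float],
    genome_wide: list[float],
    tolerance: float = 0.5,
    min_group: int = 3,
) -> tuple[float, float]:
    """Grouped fraction inside the locus versus genome-wide."""
    return (
        grouped_fraction(in_locus, tolerance, min_group),
        grouped_fraction(genome_wide, tolerance, min_group),
    )
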