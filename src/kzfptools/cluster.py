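"""Cluster loci, fingerprint repertoires, duplicated gene blocks, census.

The cluster locus is the interval strictly between two anchor genes
(1 bp downstream of the upstream anchor, 1 bp upstream of the downstream
anchor), exclusive of both anchors.  Repertoires are compared by exact
ordered identity of fingerprint-array strings.  Duplicated gene blocks are
runs of at least ``min_block_len`` genes whose 3'-exon similarity groups
recur, in order or exactly inverted, at two or more non-overlapping
positions along the cluster.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from Bio import Align
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .genes import GeneModel, find_zf_exon

__all__ = [
    "ClusterLocus",
    "locate_cluster",
    "distinct_arrays",
    "RepertoireComparison",
    "compare_repertoires",
    "exon3_sequences",
    "exon3_distances",
    "similarity_groups",
    "DuplicationBlock",
    "detect_blocks",
    "conservation_census",
    "CONSERVATION_TIERS",
]


@dataclass(frozen=True)
class ClusterLocus:
    """A KZFP cluster locus; ``start``/``end`` are 1-based inclusive."""

    chromosome: str
    start: int
    end: int
    assembly: str | None = None
    anchors: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("empty cluster locus")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    # 0-based half-open view for interval arithmetic
    @property
    def start0(self) -> int:
        return self.start - 1

    @property
    def end0(self) -> int:
        return self.end

    def overlaps(self, chrom: str, start0: int, end0: int) -> bool:
        return chrom == self.chromosome and start0 < self.end0 and end0 > self.start0


def locate_cluster(
    models: list[GeneModel],
    upstream: str = "Tnfrsf8",
    downstream: str = "Miip",
    assembly: str | None = None,
) -> ClusterLocus:
    """Define the cluster locus between two anchor genes.

    Each anchor must occur exactly once (matched on gene id or ``Name``
    attribute) and both must lie on one chromosome.  The locus is the gap
    strictly between the two gene bodies, regardless of anchor strand or
    coordinate order.
    """
    def find(name: str) -> GeneModel:
        hits = [
            m for m in models
            if m.id == name or m.attributes.get("Name") == name
        ]
        if len(hits) != 1:
            raise ValueError(
                f"anchor {name!r}: expected exactly one gene, found {len(hits)}"
            )
        return hits[0]

    up, down = find(upstream), find(downstream)
    if up.chromosome != down.chromosome:
        raise ValueError("anchor genes lie on different chromosomes")
    left, right = sorted((up, down), key=lambda m: m.start)
    if left.end >= right.start:
        raise ValueError("anchor genes overlap; no locus between them")
    return ClusterLocus(
        chromosome=up.chromosome,
        start=left.end + 1,  # 1 bp after the left gene body (1-based)
        end=right.start,     # 1 bp before the right gene body (1-based)
        assembly=assembly,
        anchors=(upstream, downstream),
    )


def distinct_arrays(
    table: pd.DataFrame, coding_only: bool = True
) -> Counter:
    """Copy-number map of fingerprint-array identity strings.

    ``table`` is an :func:`~kzfptools.genes.annotate_genes`-style frame with
    ``class`` and ``fingerprint_array`` columns.  With ``coding_only`` only
    coding genes are counted, matching the repertoire definition; empty
    arrays are never counted.
    """
    sel = table
    if coding_only:
        sel = sel[sel["class"] == "coding"]
    return Counter(a for a in sel["fingerprint_array"] if a)


@dataclass
class RepertoireComparison:
    """Pairwise sharing structure of fingerprint-array repertoires."""

    per_assembly: dict[str, Counter]
    pairwise: dict[tuple[str, str], dict] = field(default_factory=dict)

    def distinct(self, name: str) -> int:
        return len(self.per_assembly[name])


def compare_repertoires(per_assembly: dict[str, Counter]) -> RepertoireComparison:
    """Compare fingerprint-array repertoires across assemblies.

    Sharing is exact identity of the array string.  For every pair the
    shared set is split into arrays present at equal versus differing copy
    number, since shared arrays often differ in representation.
    """
    if len(per_assembly) < 2:
        raise ValueError("need at least two assemblies to compare")
    cmp = RepertoireComparison(per_assembly={k: Counter(v) for k, v in per_assembly.items()})
    for a, b in combinations(per_assembly, 2):
        sa, sb = set(per_assembly[a]), set(per_assembly[b])
        shared = sa & sb
        cmp.pairwise[(a, b)] = {
            "shared": shared,
            "unique_a": sa - sb,
            "unique_b": sb - sa,
            "shared_equal_copy": {
                k for k in shared if per_assembly[a][k] == per_assembly[b][k]
            },
            "shared_diff_copy": {
                k for k in shared if per_assembly[a][k] != per_assembly[b][k]
            },
        }
    return cmp


def exon3_sequences(
    models: list[GeneModel], genome: dict[str, str]
) -> tuple[dict[str, str], list[str]]:
    """DNA of each gene's zinc-finger (3') exon, oriented 5'->3'.

    Returns the per-gene sequences and the ids of genes excluded for
    lacking a finger-bearing exon.
    """
    from .genes import spliced_sequence

    seqs, excluded = {}, []
    for m in models:
        idx = m.zf_exon_index
        if idx is None:
            idx = find_zf_exon(m, genome)
        if idx is None:
            excluded.append(m.id)
            continue
        s, e = m.exons[idx]
        sub = GeneModel(
            id=m.id, chromosome=m.chromosome, strand=m.strand, exons=[(s, e)]
        )
        seqs[m.id] = spliced_sequence(sub, genome)
    return seqs, excluded


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -4
    a.extend_gap_score = -1
    return a


def exon3_distances(seqs: dict[str, str]) -> pd.DataFrame:
    """Pairwise 3'-exon distance matrix.

    distance = 1 - identity of one optimal global alignment (match +1,
    mismatch -1, gap open -4, gap extend -1), identity = matched columns /
    total alignment columns.  The matrix is symmetric with a zero diagonal.
    """
    ids = list(seqs)
    n = len(ids)
    mat = np.zeros((n, n))
    aligner = _aligner()
    for i, j in combinations(range(n), 2):
        aln = aligner.align(seqs[ids[i]], seqs[ids[j]])[0]
        counts = aln.counts()
        ident = counts.identities / aln.length
        mat[i, j] = mat[j, i] = 1.0 - ident
    return pd.DataFrame(mat, index=ids, columns=ids)


def similarity_groups(
    distances: pd.DataFrame,
    threshold: float = 0.05,
    positions: dict[str, int] | None = None,
) -> dict[str, int]:
    """Single-linkage groups cut at ``threshold``.

    Group labels are deterministic integers ordered by the leftmost member
    coordinate (``positions``; falls back to matrix row order).
    """
    ids = list(distances.index)
    if len(ids) == 1:
        return {ids[0]: 0}
    condensed = squareform(distances.values, checks=False)
    z = linkage(condensed, method="single")
    raw = fcluster(z, t=threshold, criterion="distance")
    pos = positions or {g: i for i, g in enumerate(ids)}
    leftmost: dict[int, int] = {}
    for g, lab in zip(ids, raw):
        leftmost[lab] = min(leftmost.get(lab, np.iinfo(np.int64).max), pos[g])
    order = {lab: rank for rank, lab in enumerate(sorted(leftmost, key=leftmost.get))}
    return {g: order[lab] for g, lab in zip(ids, raw)}


@dataclass
class DuplicationBlock:
    """A gene block found at >=2 non-overlapping cluster positions."""

    block_id: str
    labels: tuple[int, ...]
    member_ids: list[str]                       # genes of the source occurrence
    occurrences: list[dict]                     # gene index range, interval, orientation

    @property
    def n_genes(self) -> int:
        return len(self.labels)


def detect_blocks(
    genes: list[tuple[str, int, tuple[int, int]]],
    min_block_len: int = 3,
) -> tuple[list[DuplicationBlock], list[DuplicationBlock]]:
    """Detect duplicated gene blocks from ordered group labels.

    ``genes`` is an ordered list of ``(gene_id, group_label, (start, end))``
    sorted by cluster coordinate.  A block is a maximal label subsequence of
    length >= ``min_block_len`` occurring, in order or exactly reversed, at
    >=2 non-overlapping positions.  Overlapping candidates are resolved
    longest-first, ties by leftmost occurrence.  Length-2 candidates are
    returned separately as partial-duplication candidates, not blocks.

    Returns ``(blocks, partial_candidates)``.
    """
    labels = [g[1] for g in genes]
    n = len(labels)
    cands: dict[tuple[int, ...], dict] = {}

    def add(seq: tuple[int, ...], occ: tuple[int, int, str]) -> None:
        canon = min(seq, seq[::-1])
        entry = cands.setdefault(canon, {"occ": set()})
        # record orientation relative to the canonical ordering
        i, k, orient = occ
        if seq != canon:
            orient = "-" if orient == "+" else "+"
        entry["occ"].add((i, k, orient))

    # forward maximal repeats
    for i in range(n):
        for j in range(i + 1, n):
            if labels[i] != labels[j]:
                continue
            if i > 0 and labels[i - 1] == labels[j - 1]:
                continue  # not left-maximal
            k = 0
            while i + k < j and j + k < n and labels[i + k] == labels[j + k]:
                k += 1
            if k >= 2:
                seq = tuple(labels[i : i + k])
                add(seq, (i, k, "+"))
                add(seq, (j, k, "+"))
    # inverted maximal repeats: seq at i matches reversed seq ending at j2
    for i in range(n):
        for j2 in range(i + 1, n):
            if labels[i] != labels[j2]:
                continue
            k = 0
            while (
                i + k <= j2 - k
                and labels[i + k] == labels[j2 - k]
                and i + k < j2 - k
            ):
                k += 1
            if k >= 2:
                seq = tuple(labels[i : i + k])
                if seq == seq[::-1]:
                    continue  # palindromic label runs are not informative
                add(seq, (i, k, "+"))
                add(seq, (j2 - k + 1, k, "-"))

    ordered = sorted(
        cands.items(),
        key=lambda kv: (-len(kv[0]), min(o[0] for o in kv[1]["occ"])),
    )
    used = [False] * n
    blocks: list[DuplicationBlock] = []
    partials: list[DuplicationBlock] = []
    n_blocks = 0
    for seq, entry in ordered:
        occs = sorted(entry["occ"])
        free = []
        for (i, k, orient) in occs:
            if not any(used[i : i + k]):
                free.append((i, k, orient))
        # occurrences themselves must not overlap each other
        accepted: list[tuple[int, int, str]] = []
        last_end = -1
        for (i, k, orient) in free:
            if i > last_end:
                accepted.append((i, k, orient))
                last_end = i + k - 1
        if len(accepted) < 2:
            continue
        occ_dicts = []
        for (i, k, orient) in accepted:
            occ_dicts.append(
                {
                    "gene_index_start": i,
                    "gene_index_end": i + k - 1,
                    "interval": (genes[i][2][0], genes[i + k - 1][2][1]),
                    "orientation": orient,
                    "gene_ids": [genes[i + m][0] for m in range(k)],
                }
            )
        block = DuplicationBlock(
            block_id="",
            labels=seq,
            member_ids=occ_dicts[0]["gene_ids"],
            occurrences=occ_dicts,
        )
        if len(seq) >= min_block_len:
            n_blocks += 1
            block.block_id = f"block{n_blocks}"
            for (i, k, _) in accepted:
                for m in range(i, i + k):
                    used[m] = True
            blocks.append(block)
        elif len(seq) == 2:
            block.block_id = f"partial{len(partials) + 1}"
            partials.append(block)
    return blocks, partials


CONSERVATION_TIERS = (
    "species-unique",
    "clade-shared",
    "mammal-shared",
    "beyond-mammal",
)


def conservation_census(
    units: dict[str, Counter],
    clades: dict[str, str],
    mammal: dict[str, bool],
) -> pd.DataFrame:
    """Per-species conservation-tier counts of KZFP units.

    ``units`` maps species -> unit-id multiset (multiplicity = number of
    KZFP units sharing the id in that species).  Each unit in a species is
    assigned the narrowest applicable tier: unique to the species; shared
    with >=1 same-clade species and absent outside the clade; shared with
    >=1 other mammalian species but absent beyond mammals; shared beyond
    mammals.  Counts include multiplicity.
    """
    for sp in units:
        if sp not in clades:
            raise ValueError(f"species {sp!r} missing from clade map")
        if sp not in mammal:
            raise ValueError(f"species {sp!r} missing from mammal map")
    rows = []
    for sp, counter in units.items():
        tiers = Counter()
        for unit, mult in counter.items():
            others = [o for o in units if o != sp and unit in units[o]]
            if not others:
                tier = "species-unique"
            elif any(not mammal[o] for o in others):
                tier = "beyond-mammal"
            elif any(clades[o] != clades[sp] for o in others):
                tier = "mammal-shared"
            else:
                tier = "clade-shared"
            tiers[tier] += mult
        row = {"species": sp}
        row.update({t: tiers.get(t, 0) for t in CONSERVATION_TIERS})
        rows.append(row)
    return pd.DataFrame(rows).set_index("species")
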