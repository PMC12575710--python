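"""End-to-end validation studies on synthetic genomes.

Each function here runs one self-contained study at its standard
conditions and returns summary statistics.  The test suite asserts on
these numbers and the reproduction script reports them, so the study
conditions live in exactly one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cluster import (
    detect_blocks,
    exon3_distances,
    exon3_sequences,
    locate_cluster,
    similarity_groups,
)
from .curation import curate, orient_and_emit
from .fingers import scan_c2h2
from .genes import classify_transcript, fingerprint_array
from .repeats import (
    PermutationConfig,
    duplication_contrast,
    enrichment,
    family_representation,
    permutation_overlap_test,
)
from .simulate import (
    DuplicationEvent,
    SimulationConfig,
    apply_segmental_duplication,
    block_interval_for_genes,
    build_cluster_genome,
    fragment_into_contigs,
    te_bearing_block,
)

__all__ = [
    "fingerprint_rule_agreement",
    "roundtrip_recovery",
    "block_recovery",
    "null_calibration",
    "duplication_signature_study",
    "curation_study",
]


# ---------------------------------------------------------------------------
# fingerprint rule vs 12-mer index oracle
# ---------------------------------------------------------------------------

def _random_canonical_finger(rng: np.random.Generator) -> str:
    """A canonical C-X2-C-X12-H-X3-H finger with random spacer residues."""
    alphabet = "ARNDEQGIKLMFPSTWYV"  # 18 residues, no C/H
    def draw(n: int) -> str:
        return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))

    return "AG" + "C" + draw(2) + "C" + draw(12) + "H" + draw(3) + "H" + "AG"


def fingerprint_rule_agreement(n: int = 10_000, seed: int = 0) -> float:
    """Fraction of random canonical fingers where H-side anchoring agrees
    with the brute-force 12-mer spacer index oracle (positions 6, 8, 9, 12,
    1-based)."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n):
        prot = _random_canonical_finger(rng)
        fingers = scan_c2h2(prot)
        if len(fingers) != 1:
            continue
        zf = fingers[0]
        spacer = zf.spacer
        oracle = spacer[5] + spacer[7] + spacer[8] + spacer[11]
        agree += zf.fingerprint == oracle
    return agree / n


# ---------------------------------------------------------------------------
# generator round-trip
# ---------------------------------------------------------------------------

@dataclass
class RoundtripResult:
    n_genes: int = 0
    n_class_ok: int = 0
    n_array_ok: int = 0
    n_distinct_ok: int = 0
    n_sims: int = 0

    @property
    def recovery_fraction(self) -> float:
        return min(self.n_class_ok, self.n_array_ok) / max(self.n_genes, 1)


def roundtrip_recovery(seeds: range = range(20)) -> RoundtripResult:
    """Recover class and fingerprint array of every planted coding gene
    across seeded simulations; also checks distinct-array counts."""
    res = RoundtripResult(n_sims=len(seeds))
    for seed in seeds:
        sim = build_cluster_genome(SimulationConfig(seed=seed))
        models = {m.id: m for m in sim.models}
        truth_arrays = []
        for rec in sim.truth.genes:
            if rec.origin != "planted" or rec.gene_class != "coding":
                continue
            res.n_genes += 1
            m = models[rec.id]
            if classify_transcript(m, sim.sequences) == "coding":
                res.n_class_ok += 1
            arr = fingerprint_array(m, sim.sequences).key
            if arr == rec.fingerprint_key:
                res.n_array_ok += 1
            truth_arrays.append(rec.fingerprint_key)
        from collections import Counter

        from .genes import annotate_genes

        planted_ids = {
            r.id for r in sim.truth.genes
            if r.origin == "planted" and r.gene_class == "coding"
        }
        table = annotate_genes(
            [models[i] for i in sorted(planted_ids)], sim.sequences
        )
        from .cluster import distinct_arrays

        if distinct_arrays(table) == Counter(truth_arrays):
            res.n_distinct_ok += 1
    return res


# ---------------------------------------------------------------------------
# block recovery
# ---------------------------------------------------------------------------

@dataclass
class BlockRecoveryResult:
    n_planted: int = 0
    n_recovered: int = 0
    n_spurious: int = 0
    per_seed: list[tuple[int, int, int, int]] = field(default_factory=list)

    @property
    def recovery_fraction(self) -> float:
        return self.n_recovered / max(self.n_planted, 1)


def _block_events(rng: np.random.Generator, n_genes: int) -> list[DuplicationEvent]:
    """1-3 non-overlapping duplication events of 3-7 genes each."""
    n_events = int(rng.integers(1, 4))
    events = []
    taken: list[tuple[int, int]] = []
    for _ in range(n_events):
        for _attempt in range(20):
            size = int(rng.integers(3, 8))
            first = int(rng.integers(0, n_genes - size + 1))
            last = first + size - 1
            # keep a 1-gene margin between event ranges
            if all(last < s - 1 or first > e + 1 for s, e in taken):
                taken.append((first, last))
                events.append(
                    DuplicationEvent(
                        first, last,
                        rounds=int(rng.integers(1, 3)),
                        post_rate=float(rng.uniform(0.0, 0.02)),
                    )
                )
                break
    return events


def block_recovery(
    seeds: range = range(20),
    n_genes: int = 30,
    threshold: float = 0.05,
) -> BlockRecoveryResult:
    """Plant 1-3 gene blocks per simulation and recover them from 3'-exon
    similarity grouping; boundaries must match within +/-1 gene and no
    unplanted block of >=3 genes may be reported."""
    out = BlockRecoveryResult()
    for seed in seeds:
        meta_rng = np.random.default_rng(10_000 + seed)
        events = _block_events(meta_rng, n_genes)
        cfg = SimulationConfig(
            seed=seed, n_kzfp_genes=n_genes, duplication_events=events,
        )
        sim = build_cluster_genome(cfg)
        kzfp = sorted(sim.kzfp_models, key=lambda m: m.start)
        exons, _ = exon3_sequences(kzfp, sim.sequences)
        dist = exon3_distances(exons)
        pos = {m.id: m.start for m in kzfp}
        groups = similarity_groups(dist, threshold, positions=pos)
        gene_list = [(m.id, groups[m.id], (m.start, m.end)) for m in kzfp]
        found, _ = detect_blocks(gene_list, min_block_len=3)

        index_of = {m.id: i for i, m in enumerate(kzfp)}
        planted_ranges: list[list[tuple[int, int]]] = []
        for block in sim.truth.blocks:
            occs = [_index_range(block.gene_ids, index_of)]
            rounds = max(
                int(g.id.rsplit("r", 1)[1])
                for g in sim.truth.genes
                if g.origin == "duplication" and g.block_id == block.id
            )
            for rnd in range(1, rounds + 1):
                dup_ids = [
                    g.id for g in sim.truth.genes
                    if g.block_id == block.id
                    and g.origin == "duplication"
                    and g.id.endswith(f"{block.id}r{rnd}")
                ]
                occs.append(_index_range(dup_ids, index_of))
            planted_ranges.append(occs)

        detected_occs = [
            [(o["gene_index_start"], o["gene_index_end"]) for o in b.occurrences]
            for b in found
        ]
        recovered = 0
        matched_det = set()
        for occs in planted_ranges:
            out.n_planted += 1
            for di, docc in enumerate(detected_occs):
                if _occurrences_match(occs, docc, slack=1):
                    recovered += 1
                    matched_det.add(di)
                    break
        spurious = len(detected_occs) - len(matched_det)
        out.n_recovered += recovered
        out.n_spurious += spurious
        out.per_seed.append((seed, len(planted_ranges), recovered, spurious))
    return out


def _index_range(gene_ids: list[str], index_of: dict[str, int]) -> tuple[int, int]:
    idx = sorted(index_of[g] for g in gene_ids if g in index_of)
    return idx[0], idx[-1]


def _occurrences_match(
    planted: list[tuple[int, int]],
    detected: list[tuple[int, int]],
    slack: int = 1,
) -> bool:
    """Every planted occurrence matched by a detected one within slack."""
    used = set()
    for ps, pe in planted:
        hit = None
        for i, (ds, de) in enumerate(detected):
            if i in used:
                continue
            if abs(ds - ps) <= slack and abs(de - pe) <= slack:
                hit = i
                break
        if hit is None:
            return False
        used.add(hit)
    return True


# ---------------------------------------------------------------------------
# permutation-null calibration
# ---------------------------------------------------------------------------

def null_calibration(
    n_datasets: int = 500,
    n_regions: int = 300,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Fraction of null datasets with p <= 0.05.

    Regions are drawn from the permutation null itself (uniform starts,
    lengths 100-500 on a 100 kb chromosome, locus 10 kb), so the p-value
    should be uniform up to the discreteness of overlap counts.
    """
    from .cluster import ClusterLocus

    rng = np.random.default_rng(seed)
    chrom_lengths = {"chrN": 100_000}
    locus = ClusterLocus("chrN", 20_001, 30_000)
    hits = 0
    for _ in range(n_datasets):
        lengths = rng.integers(100, 501, size=n_regions)
        starts = [
            int(rng.integers(0, chrom_lengths["chrN"] - int(l) + 1))
            for l in lengths
        ]
        regions = [
            ("chrN", s, s + int(l)) for s, l in zip(starts, lengths)
        ]
        res = permutation_overlap_test(
            regions, locus, chrom_lengths,
            PermutationConfig(n=n_perm, seed=int(rng.integers(2**31 - 1))),
        )
        hits += res.p <= 0.05
    return hits / n_datasets


# ---------------------------------------------------------------------------
# duplication-vs-insertion signature
# ---------------------------------------------------------------------------

@dataclass
class SignatureResult:
    n_seeds: int = 0
    n_enrichment_up: int = 0
    n_representation_up: int = 0
    n_contrast_up: int = 0


def duplication_signature_study(
    seeds: range = range(10),
    family: str = "ERVK10C_MM",
    rounds: int = 3,
    post_rate: float = 0.001,
) -> SignatureResult:
    """Duplicate an ERV-bearing gene block and measure the three
    signatures: locus enrichment rises, family representation rises, and
    in-locus divergence values pile into groups absent genome-wide."""
    out = SignatureResult(n_seeds=len(seeds))
    for seed in seeds:
        sim = build_cluster_genome(SimulationConfig(seed=seed))
        recs = sim.repeat_records()
        pre_e = enrichment(family, recs, sim.locus, sim.chrom_lengths())
        pre_r = family_representation(family, recs, sim.locus)
        i0, i1 = te_bearing_block(sim, family)
        block = block_interval_for_genes(sim, i0, i1)
        rng = np.random.default_rng(1_000_000 + seed)
        apply_segmental_duplication(sim, block, rounds, post_rate, rng)
        recs2 = sim.repeat_records()
        post_e = enrichment(family, recs2, sim.locus, sim.chrom_lengths())
        post_r = family_representation(family, recs2, sim.locus)
        pre_log = (
            pre_e.log2_enrichment if pre_e.log2_enrichment is not None
            else -np.inf
        )
        if post_e.log2_enrichment is not None and post_e.log2_enrichment > pre_log:
            out.n_enrichment_up += 1
        if post_r > pre_r:
            out.n_representation_up += 1
        in_locus = [
            t.percent_divergence for t in sim.truth.te_copies
            if t.family == family
            and sim.locus.overlaps(t.chromosome, t.start, t.end)
        ]
        genome_wide = [
            t.percent_divergence for t in sim.truth.te_copies
            if t.family == family
        ]
        f_in, f_gw = duplication_contrast(in_locus, genome_wide)
        if f_in > f_gw:
            out.n_contrast_up += 1
    return out


# ---------------------------------------------------------------------------
# contig curation
# ---------------------------------------------------------------------------

@dataclass
class CurationResult:
    n_seeds: int = 0
    n_nested_exact: int = 0
    n_reconstructed: int = 0


def curation_study(seeds: range = range(10)) -> CurationResult:
    """Fragment, curate, and check nested-drop exactness plus exact
    chromosome reconstruction from the curated, re-ordered contigs."""
    out = CurationResult(n_seeds=len(seeds))
    for seed in seeds:
        cfg = SimulationConfig(seed=seed)
        sim = build_cluster_genome(cfg)
        contigs = fragment_into_contigs(sim)
        decisions = curate(contigs.paf, set(sim.sequences))
        nested_truth = {
            c.name for c in sim.truth.contigs if c.nested_in is not None
        }
        dropped = {d.contig for d in decisions if d.verdict == "drop-nested"}
        if dropped == nested_truth:
            out.n_nested_exact += 1
        curated, report = orient_and_emit(contigs.sequences, decisions)
        kept = report[report["verdict"] == "keep"].sort_values(
            ["chromosome", "span_start"]
        )
        rebuilt: dict[str, str] = {}
        for _, row in kept.iterrows():
            rebuilt[row["chromosome"]] = (
                rebuilt.get(row["chromosome"], "") + curated[row["contig"]]
            )
        if all(rebuilt.get(c) == s for c, s in sim.sequences.items()):
            out.n_reconstructed += 1
    return out
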