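"""Synthetic-genome generator: construction, duplication, fragmentation."""

import filecmp

import numpy as np
import pytest

from kzfptools.fingers import scan_c2h2
from kzfptools.repeats import read_repeatmasker_out
from kzfptools.simulate import (
    DuplicationEvent,
    SimulationConfig,
    apply_segmental_duplication,
    block_interval_for_genes,
    build_cluster_genome,
    fragment_into_contigs,
    make_kzfp_gene,
)

from conftest import small_config


class TestMakeGene:
    def test_single_finger_roundtrip(self):
        rng = np.random.default_rng(0)
        parts = make_kzfp_gene(rng, 1)
        fingers = scan_c2h2(parts.protein)
        assert len(fingers) == 1
        assert fingers[0].fingerprint == parts.fingerprints[0]

    def test_degenerate_finger_flagged(self):
        rng = np.random.default_rng(0)
        parts = make_kzfp_gene(rng, 5, degenerate_positions=[3])
        fingers = scan_c2h2(parts.protein)
        assert len(fingers) == 5
        assert [f.flag_ch_mutation for f in fingers] == [
            False, False, False, True, False,
        ]
        assert [f.fingerprint for f in fingers] == parts.fingerprints

    def test_same_seed_identical(self):
        a = make_kzfp_gene(np.random.default_rng(9), 6)
        b = make_kzfp_gene(np.random.default_rng(9), 6)
        assert a.dna == b.dna and a.protein == b.protein

    def test_invalid_finger_count(self):
        with pytest.raises(ValueError, match="at least one"):
            make_kzfp_gene(np.random.default_rng(0), 0)


class TestBuildGenome:
    def test_zero_genes_leaves_only_anchors(self):
        sim = build_cluster_genome(small_config(n_kzfp_genes=0))
        names = {g.id for g in sim.truth.genes}
        assert names == set(sim.config.anchor_gene_names)

    def test_feature_counts_match_truth(self, small_sim, tmp_path):
        cfg = small_sim.config
        n_gene_records = len(
            [g for g in small_sim.truth.genes if g.gene_class != "non-kzfp"]
        )
        assert n_gene_records == cfg.n_kzfp_genes
        small_sim.write(tmp_path)
        gff_genes = sum(
            1 for line in open(tmp_path / "genes.gff3")
            if "\tgene\t" in line
        )
        assert gff_genes == cfg.n_kzfp_genes + 2  # plus the two anchors
        records = read_repeatmasker_out(tmp_path / "repeats.out")
        assert len(records) == len(small_sim.truth.te_copies)
        assert len(records) == sum(f.copy_number for f in cfg.te_families)

    def test_anchor_genes_flank_the_cluster(self, small_sim):
        anchors = [
            g for g in small_sim.truth.genes if g.gene_class == "non-kzfp"
        ]
        kzfp = [g for g in small_sim.truth.genes if g.gene_class != "non-kzfp"]
        left, right = sorted(a.start for a in anchors)
        assert all(left < g.start < right for g in kzfp)
        assert small_sim.locus.start == sorted(a.end for a in anchors)[0] + 1

    def test_divergence_binomial_oracle(self):
        """Realized divergence of each copy stays within 3 sd of the
        Poisson substitution expectation at the configured mean."""
        from kzfptools.simulate import TEFamilySpec

        cfg = small_config(
            seed=3,
            te_families=[TEFamilySpec("TEST_FAM", "LTR", 500, 30, 5.0, 0.0)],
        )
        sim = build_cluster_genome(cfg)
        sd = 100 * np.sqrt(500 * 0.05) / 500  # percent points
        for t in sim.truth.te_copies:
            assert abs(t.percent_divergence - 5.0) <= 3 * sd

    def test_divergence_mean_within_3se(self):
        sim = build_cluster_genome(small_config(seed=4))
        for fam in sim.config.te_families:
            divs = [
                t.percent_divergence for t in sim.truth.te_copies
                if t.family == fam.name
            ]
            se = np.std(divs, ddof=1) / np.sqrt(len(divs))
            assert abs(np.mean(divs) - fam.mean_divergence) <= 3 * max(se, 1.0)

    def test_byte_identical_outputs_for_same_config(self, tmp_path):
        for d in ("a", "b"):
            sim = build_cluster_genome(small_config(seed=11))
            fragment_into_contigs(sim)
            sim.write(tmp_path / d)
        for name in ("genome.fa", "genes.gff3", "repeats.out",
                     "truth_genes.tsv", "truth_te_copies.tsv",
                     "truth_contigs.tsv"):
            assert filecmp.cmp(
                tmp_path / "a" / name, tmp_path / "b" / name, shallow=False
            ), name

    def test_layout_error_when_features_do_not_fit(self):
        with pytest.raises(ValueError):
            build_cluster_genome(
                small_config(chrom_lengths={"chr1": 30_000, "chr2": 80_000})
            )


class TestDuplication:
    def test_zero_rate_copy_is_byte_identical(self):
        sim = build_cluster_genome(small_config(seed=2))
        pre_tes = {t.id: t.percent_divergence for t in sim.truth.te_copies}
        block = block_interval_for_genes(sim, 1, 3)
        rng = np.random.default_rng(0)
        apply_segmental_duplication(sim, block, 1, 0.0, rng)
        (blk,) = sim.truth.blocks
        s0, e0 = blk.source
        s1, e1 = blk.copies[0]
        chrom = sim.sequences[sim.locus.chromosome]
        assert chrom[s0:e0] == chrom[s1:e1]
        for t in sim.truth.te_copies:
            if t.origin == "duplication":
                assert t.percent_divergence == pre_tes[t.parent]

    def test_duplicate_record_counting(self):
        sim = build_cluster_genome(small_config(seed=2))
        block = block_interval_for_genes(sim, 0, 3)  # 4 genes
        apply_segmental_duplication(sim, block, 2, 0.0, np.random.default_rng(1))
        dups = [g for g in sim.truth.genes if g.origin == "duplication"]
        assert len(dups) == 8
        assert all(d.parent is not None for d in dups)

    def test_cluster_grows_by_rounds_times_block_length(self):
        sim = build_cluster_genome(small_config(seed=2))
        pre = len(sim.sequences[sim.locus.chromosome])
        block = block_interval_for_genes(sim, 1, 2)
        L = block[1] - block[0]
        apply_segmental_duplication(sim, block, 3, 0.01, np.random.default_rng(2))
        assert len(sim.sequences[sim.locus.chromosome]) == pre + 3 * L

    def test_copy_identity_matches_binomial_rate(self):
        sim = build_cluster_genome(small_config(seed=6))
        block = block_interval_for_genes(sim, 0, 4)
        L = block[1] - block[0]
        apply_segmental_duplication(sim, block, 1, 0.02, np.random.default_rng(3))
        (blk,) = sim.truth.blocks
        chrom = sim.sequences[sim.locus.chromosome]
        src = chrom[blk.source[0] : blk.source[1]]
        cpy = chrom[blk.copies[0][0] : blk.copies[0][1]]
        ident = sum(a == b for a, b in zip(src, cpy)) / L
        tol = 3 * np.sqrt(0.02 * 0.98 / L)
        assert ident == pytest.approx(0.98, abs=tol)

    def test_block_overlapping_anchor_refused(self):
        sim = build_cluster_genome(small_config(seed=2))
        anchor = next(
            m for m in sim.models if m.attributes.get("Name") == "Tnfrsf8"
        )
        with pytest.raises(ValueError):
            apply_segmental_duplication(
                sim, (anchor.start, sim.locus.end0 - 1000), 1, 0.0,
                np.random.default_rng(0),
            )


class TestFragmentation:
    def test_no_breaks_one_contig_per_chromosome(self):
        from kzfptools.simulate import FragmentationSpec

        cfg = small_config(
            seed=1, fragmentation=FragmentationSpec(0, 0.0, 0)
        )
        sim = build_cluster_genome(cfg)
        cs = fragment_into_contigs(sim)
        assert len(cs.sequences) == len(sim.sequences)
        assert all(r.strand == "+" for r in cs.paf)

    def test_flip_probability_one_flips_everything(self):
        from kzfptools.simulate import FragmentationSpec

        cfg = small_config(
            seed=1, fragmentation=FragmentationSpec(4, 1.0, 0)
        )
        sim = build_cluster_genome(cfg)
        cs = fragment_into_contigs(sim)
        assert all(r.strand == "-" for r in cs.paf)

    def test_contigs_tile_genome_without_overlap(self):
        sim = build_cluster_genome(small_config(seed=8))
        fragment_into_contigs(sim)
        by_chrom = {}
        for c in sim.truth.contigs:
            if c.nested_in is None:
                by_chrom.setdefault(c.chromosome, []).append((c.start, c.end))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            assert ivs[0][0] == 0
            assert ivs[-1][1] == len(sim.sequences[chrom])
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 == s2
        total = sum(
            c.end - c.start for c in sim.truth.contigs if c.nested_in is None
        )
        assert total == sum(len(s) for s in sim.sequences.values())

    def test_nested_extras_are_proper_subintervals(self):
        sim = build_cluster_genome(small_config(seed=8))
        fragment_into_contigs(sim)
        by_name = {c.name: c for c in sim.truth.contigs}
        nested = [c for c in sim.truth.contigs if c.nested_in]
        assert len(nested) == sim.config.fragmentation.n_nested_extras
        for c in nested:
            parent = by_name[c.nested_in]
            assert parent.start <= c.start and c.end <= parent.end
            assert (c.end - c.start) < (parent.end - parent.start)
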