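"""Locus definition, repertoires, block detection, conservation census."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from kzfptools.cluster import (
    compare_repertoires,
    conservation_census,
    detect_blocks,
    distinct_arrays,
    exon3_distances,
    locate_cluster,
    similarity_groups,
)
from kzfptools.genes import GeneModel


def gene(gid, chrom, start, end, strand="+", name=None):
    return GeneModel(
        id=gid, chromosome=chrom, strand=strand, exons=[(start, end)],
        attributes={"Name": name or gid},
    )


class TestLocateCluster:
    def test_interval_between_anchor_bodies(self):
        models = [
            gene("Tnfrsf8", "chr4", 99, 200),   # 1-based [100, 200]
            gene("Miip", "chr4", 999, 1100),    # 1-based [1000, 1100]
        ]
        locus = locate_cluster(models)
        assert (locus.start, locus.end) == (201, 999)
        assert locus.length == 799

    def test_strand_and_order_invariance(self):
        fwd = [
            gene("Tnfrsf8", "chr4", 99, 200, "-"),
            gene("Miip", "chr4", 999, 1100, "-"),
        ]
        swapped = [
            gene("Miip", "chr4", 99, 200),
            gene("Tnfrsf8", "chr4", 999, 1100),
        ]
        assert locate_cluster(fwd).start == 201
        locus = locate_cluster(swapped)
        assert (locus.start, locus.end) == (201, 999)

    def test_missing_or_duplicated_anchor_errors(self):
        models = [gene("Tnfrsf8", "chr4", 0, 10)]
        with pytest.raises(ValueError, match="anchor"):
            locate_cluster(models)
        models += [
            gene("Miip", "chr4", 100, 110),
            gene("g3", "chr4", 200, 210, name="Miip"),
        ]
        with pytest.raises(ValueError, match="anchor"):
            locate_cluster(models)

    def test_synthetic_locus_contains_exactly_the_planted_genes(self, small_sim):
        locus = locate_cluster(small_sim.models)
        assert locus == small_sim.locus
        for g in small_sim.truth.genes:
            if g.gene_class == "non-kzfp":
                continue
            assert locus.start0 <= g.start and g.end <= locus.end0


class TestRepertoires:
    def table(self, arrays, classes=None):
        classes = classes or ["coding"] * len(arrays)
        return pd.DataFrame(
            {"fingerprint_array": arrays, "class": classes}
        )

    def test_distinct_array_counting(self):
        counts = distinct_arrays(self.table(["A", "A", "B"]))
        assert counts == Counter({"A": 2, "B": 1})

    def test_coding_only_filter(self):
        t = self.table(["A", "A", "B"], ["coding", "pseudogene", "coding"])
        assert distinct_arrays(t) == Counter({"A": 1, "B": 1})
        assert distinct_arrays(t, coding_only=False) == Counter({"A": 2, "B": 1})

    def test_identical_assemblies_fully_shared(self):
        maps = {"x": Counter({"A": 2, "B": 1}), "y": Counter({"A": 1, "B": 3})}
        cmp = compare_repertoires(maps)
        d = cmp.pairwise[("x", "y")]
        assert d["shared"] == {"A", "B"}
        assert not d["unique_a"] and not d["unique_b"]
        assert d["shared_equal_copy"] == set()
        assert d["shared_diff_copy"] == {"A", "B"}

    def test_disjoint_assemblies_share_nothing(self):
        maps = {"x": Counter({"A": 1}), "y": Counter({"B": 1})}
        d = compare_repertoires(maps).pairwise[("x", "y")]
        assert not d["shared"]
        assert d["unique_a"] == {"A"} and d["unique_b"] == {"B"}

    def test_shared_plus_unique_partitions_distinct(self):
        rng = np.random.default_rng(0)
        universe = [f"arr{i}" for i in range(30)]
        maps = {
            name: Counter(rng.choice(universe, size=20).tolist())
            for name in ("a", "b", "c")
        }
        cmp = compare_repertoires(maps)
        for (a, b), d in cmp.pairwise.items():
            assert len(d["shared"]) + len(d["unique_a"]) == cmp.distinct(a)
            assert len(d["shared"]) + len(d["unique_b"]) == cmp.distinct(b)


class TestDistances:
    def test_identical_and_mutated_exons(self):
        rng = np.random.default_rng(0)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
        mutated = list(seq)
        idx = rng.choice(1000, size=20, replace=False)
        for i in idx:
            mutated[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[i]]
        d = exon3_distances({"a": seq, "b": "".join(mutated), "c": seq})
        assert d.loc["a", "c"] == 0.0
        assert d.loc["a", "a"] == 0.0
        assert d.loc["a", "b"] == pytest.approx(0.02, abs=3 * np.sqrt(0.02 * 0.98 / 1000))

    def test_unrelated_sequences_are_distant(self):
        rng = np.random.default_rng(1)
        seqs = {
            k: "".join("ACGT"[i] for i in rng.integers(0, 4, 800))
            for k in "ab"
        }
        d = exon3_distances(seqs)
        assert d.loc["a", "b"] > 0.5

    def test_matrix_symmetry(self):
        rng = np.random.default_rng(2)
        seqs = {
            k: "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
            for k in "abcd"
        }
        d = exon3_distances(seqs)
        assert np.allclose(d.values, d.values.T)


class TestGroups:
    def test_all_zero_distances_one_group(self):
        d = pd.DataFrame(np.zeros((4, 4)), index=list("abcd"), columns=list("abcd"))
        assert set(similarity_groups(d).values()) == {0}

    def test_all_far_distances_singletons(self):
        m = np.ones((4, 4)) - np.eye(4)
        d = pd.DataFrame(m, index=list("abcd"), columns=list("abcd"))
        groups = similarity_groups(d)
        assert len(set(groups.values())) == 4

    def test_labels_ordered_by_leftmost_position(self):
        m = np.array(
            [[0.0, 0.9, 0.01], [0.9, 0.0, 0.9], [0.01, 0.9, 0.0]]
        )
        d = pd.DataFrame(m, index=list("abc"), columns=list("abc"))
        groups = similarity_groups(d, positions={"a": 100, "b": 10, "c": 200})
        # b is leftmost -> label 0; {a, c} next
        assert groups["b"] == 0 and groups["a"] == groups["c"] == 1


class TestDetectBlocks:
    def run(self, labels, min_len=3):
        genes = [
            (f"g{i}", lab, (i * 100, i * 100 + 50))
            for i, lab in enumerate(labels)
        ]
        return detect_blocks(genes, min_block_len=min_len)

    def test_tandem_repeat_of_three(self):
        blocks, _ = self.run(list("ABCDABC"))
        assert len(blocks) == 1
        (b,) = blocks
        assert b.labels == tuple("ABC")
        assert [o["gene_index_start"] for o in b.occurrences] == [0, 4]

    def test_no_repeats_no_blocks(self):
        blocks, partial = self.run(list("ABCDEFG"))
        assert blocks == [] and partial == []

    def test_inverted_occurrence_detected(self):
        blocks, _ = self.run(list("ABCXXCBA"))
        assert len(blocks) == 1
        (b,) = blocks
        orients = sorted(o["orientation"] for o in b.occurrences)
        assert orients == ["+", "-"]

    def test_length_two_reported_as_partial_not_block(self):
        blocks, partial = self.run(list("ABXAB"))
        assert blocks == []
        assert len(partial) == 1
        assert partial[0].labels == ("A", "B")

    def test_three_occurrences_merged(self):
        blocks, _ = self.run(list("ABCxABCyABC"))
        (b,) = blocks
        assert len(b.occurrences) == 3

    def test_translation_invariance(self):
        labels = list("ABCDABC")
        g1 = [(f"g{i}", l, (i * 100, i * 100 + 50)) for i, l in enumerate(labels)]
        g2 = [
            (f"g{i}", l, (10_000 + i * 100, 10_000 + i * 100 + 50))
            for i, l in enumerate(labels)
        ]
        b1, _ = detect_blocks(g1)
        b2, _ = detect_blocks(g2)
        assert [b.labels for b in b1] == [b.labels for b in b2]
        assert [
            [(o["gene_index_start"], o["gene_index_end"]) for o in b.occurrences]
            for b in b1
        ] == [
            [(o["gene_index_start"], o["gene_index_end"]) for o in b.occurrences]
            for b in b2
        ]


class TestThreeStrains:
    def test_sharing_structure_follows_lineage(self):
        """Three strains derived from one ancestor by independent block
        duplications share the ancestral repertoire; arrays created by
        post-duplication mutation are strain-unique."""
        import copy

        import numpy as np

        from kzfptools.genes import annotate_genes
        from kzfptools.simulate import (
            apply_segmental_duplication,
            block_interval_for_genes,
            build_cluster_genome,
        )

        from conftest import small_config

        ancestor = build_cluster_genome(small_config(seed=12))
        ancestral_arrays = {
            g.fingerprint_key for g in ancestor.truth.genes
            if g.gene_class == "coding"
        }
        repertoires = {}
        for strain in range(3):
            sim = copy.deepcopy(ancestor)
            rng = np.random.default_rng(500 + strain)
            first = strain  # different block per strain
            block = block_interval_for_genes(sim, first, first + 2)
            apply_segmental_duplication(sim, block, 1, 0.01, rng)
            table = annotate_genes(sim.kzfp_models, sim.sequences)
            repertoires[f"s{strain}"] = distinct_arrays(table)
        cmp = compare_repertoires(repertoires)
        for (a, b), d in cmp.pairwise.items():
            # everything shared between strains is ancestral
            assert d["shared"] <= ancestral_arrays
            assert ancestral_arrays <= set(repertoires[a]) | d["shared"]
            # strain-unique arrays arise only from mutated duplicates
            for arr in d["unique_a"] | d["unique_b"]:
                assert arr not in ancestral_arrays


def census_oracle(units, clades, mammal):
    """Brute-force tier assignment by explicit set membership."""
    out = {}
    for sp in units:
        tiers = Counter()
        for unit, mult in units[sp].items():
            carriers = {o for o in units if unit in units[o]}
            others = carriers - {sp}
            if not others:
                t = "species-unique"
            elif others - {o for o in others if mammal[o]}:
                t = "beyond-mammal"
            elif {o for o in others if clades[o] != clades[sp]}:
                t = "mammal-shared"
            else:
                t = "clade-shared"
            tiers[t] += mult
        out[sp] = tiers
    return out


class TestCensus:
    def test_single_species_all_unique(self):
        res = conservation_census(
            {"mouse": Counter({"u1": 2, "u2": 1})},
            {"mouse": "rodent"},
            {"mouse": True},
        )
        assert res.loc["mouse", "species-unique"] == 3
        assert res.loc["mouse", "clade-shared"] == 0

    def test_same_clade_sharing(self):
        units = {
            "mouse": Counter({"u1": 1, "u2": 1}),
            "rat": Counter({"u1": 1}),
        }
        res = conservation_census(
            units,
            {"mouse": "rodent", "rat": "rodent"},
            {"mouse": True, "rat": True},
        )
        assert res.loc["mouse", "clade-shared"] == 1
        assert res.loc["mouse", "species-unique"] == 1
        assert res.loc["rat", "clade-shared"] == 1

    def test_missing_species_in_clade_map_errors(self):
        with pytest.raises(ValueError, match="clade"):
            conservation_census(
                {"mouse": Counter({"u": 1})}, {}, {"mouse": True}
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_random_tables_match_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        species = ["mouse", "rat", "gerbil", "human", "macaque", "chicken"]
        clades = {
            "mouse": "rodent", "rat": "rodent", "gerbil": "rodent",
            "human": "primate", "macaque": "primate", "chicken": "bird",
        }
        mammal = {s: s != "chicken" for s in species}
        units = {
            sp: Counter(
                {
                    f"u{i}": int(rng.integers(1, 4))
                    for i in range(50)
                    if rng.random() < 0.3
                }
            )
            for sp in species
        }
        res = conservation_census(units, clades, mammal)
        oracle = census_oracle(units, clades, mammal)
        for sp in species:
            for tier in res.columns:
                assert res.loc[sp, tier] == oracle[sp].get(tier, 0)
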