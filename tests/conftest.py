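import pytest

from kzfptools.simulate import (
    SimulationConfig,
    TEFamilySpec,
    build_cluster_genome,
)


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A compact configuration for fast unit tests."""
    defaults = dict(
        seed=seed,
        chrom_lengths={"chr1": 150_000, "chr2": 80_000},
        n_kzfp_genes=6,
        te_families=[
            TEFamilySpec("ERVK10C_MM", "LTR", 400, 12, 8.0, 4.0),
            TEFamilySpec("B1_Mur4", "SINE", 150, 20, 15.0, 6.0),
        ],
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_sim():
    return build_cluster_genome(small_config(seed=0))


@pytest.fixture(scope="session")
def genome(small_sim):
    return small_sim.sequences
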