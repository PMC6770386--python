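import pytest

from virotrial import fixtures, refdb, simulate


@pytest.fixture(scope="session")
def small_world():
    """A clean 10-clade world, all records passing the admission filters."""
    return fixtures.make_world(
        n_clades=10, entries_per_clade=5, genome_length=(1500, 2500), seed=42
    )


@pytest.fixture(scope="session")
def curated(small_world):
    return refdb.curate(list(small_world.records), seed=1)


@pytest.fixture(scope="session")
def contaminant_pools():
    return fixtures.make_contaminant_pool(n_human=3, n_other=5, seed=2)


@pytest.fixture(scope="session")
def stand_in_species():
    """Synthetic one-strain-per-species genomes for both built-in challenges."""
    return fixtures.species_stand_ins(
        simulate.CHALLENGE_II_SPECIES + simulate.CHALLENGE_III_SPECIES,
        genome_length=(5000, 20000),
        seed=5,
    )
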