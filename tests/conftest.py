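import numpy as np
import pytest

from fimpera.core import FimperaConfig, FimperaIndex
from fimpera.evalmetrics import GroundTruth
from fimpera.sequence_io import CountedKmerTable
from fimpera.synthetic import (
    counted_kmers_from_genome,
    generate_genome,
    geometric_abundance,
)


@pytest.fixture
def tiny_table() -> CountedKmerTable:
    """The two-entry worked example used throughout: k=5, counts 5 and 3."""
    return CountedKmerTable([("ACGTA", 5), ("CGTAC", 3)], k=5)


@pytest.fixture(scope="session")
def random_table() -> CountedKmerTable:
    """~500 distinct 21-mers from a random genome, geometric counts."""
    genome = generate_genome(520, seed=7)
    return counted_kmers_from_genome(
        genome, 21, geometric_abundance(3.0), canonical=False, seed=7
    )


@pytest.fixture(scope="session")
def collision_free_index(random_table):
    """Index sized so generously that slot collisions are essentially absent."""
    cfg = FimperaConfig(
        k=21, z=3, b=8, nb_slots=1 << 22, discretization="identity"
    )
    return FimperaIndex.build(random_table, cfg)


@pytest.fixture(scope="session")
def collision_free_truth(random_table, collision_free_index):
    return GroundTruth.from_table(random_table, collision_free_index.config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230517)
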