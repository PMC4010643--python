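import numpy as np
import pytest

from somascape.genome import Gene, GenomeModel, human_autosomes
from somascape.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def genome():
    """The default mini-genome (22 autosomes at 1/20 scale)."""
    return human_autosomes()


@pytest.fixture()
def tiny_genome():
    """A two-chromosome toy genome for hand-checkable oracle tests."""
    return GenomeModel(
        chromosomes=[("1", 1_000), ("2", 800)],
        centromeres={"1": 400, "2": 300},
        genes=[Gene("GENE1", "1", 101, 200), Gene("GENE2", "2", 501, 600)],
    )


@pytest.fixture(scope="session")
def default_cohort(genome):
    """One default synthetic cohort, shared across read-only tests."""
    return generate_cohort(CohortConfig(seed=11), genome)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
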