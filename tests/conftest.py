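import logging

import numpy as np
import pytest

from cucsyn.linkage import PopulationType
from cucsyn.simulate import marker_table, simulate_ancestral_genome, simulate_population

logging.getLogger("cucsyn").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_genome():
    """A 3-chromosome toy ancestral genome with 8 markers per chromosome."""
    return simulate_ancestral_genome(n_chrom=3, markers_per_chrom=8, seed=42)


@pytest.fixture(scope="session")
def small_panel(small_genome):
    return marker_table(small_genome)


@pytest.fixture(scope="session")
def f2_small(small_panel):
    return simulate_population(small_panel, PopulationType.F2, 200, seed=9)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
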