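import numpy as np
import pytest

from botodelim.fixtures import load_table1, load_table2
from botodelim.simulate import (SyntheticSeqSpec, study_design_pop_spec,
                                simulate_microsatellite_genotypes,
                                simulate_sequence_alignment)


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def table2():
    return load_table2()


@pytest.fixture(scope="session")
def study_genotypes():
    """Study-design synthetic genotypes: 3 groups (45/44/32), 10 loci, F=0.15."""
    return simulate_microsatellite_genotypes(study_design_pop_spec(seed=11))


@pytest.fixture(scope="session")
def three_lineage_alignment():
    """Synthetic mtDNA at the published divergence geometry and clock rate."""
    return simulate_sequence_alignment(SyntheticSeqSpec(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
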