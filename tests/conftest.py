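import numpy as np
import pytest

from aerodepo import AerosolSpec, StageTable, sample_impactor_run


@pytest.fixture
def dense_table() -> StageTable:
    """50-stage geometric grid spanning the instrument range."""
    return StageTable.geometric(0.03, 10.0, 50)


@pytest.fixture
def default_table() -> StageTable:
    return StageTable.default()


@pytest.fixture
def nl11_run(dense_table):
    """Noiseless stage integration of the micron-sized (AMAD 2.8 μm,
    GSD 3.2) log-normal aerosol."""
    return sample_impactor_run(AerosolSpec(2.8, 3.2), dense_table,
                               count_scale=1e6, noiseless=True)


@pytest.fixture
def rng():
    return np.random.default_rng(20160707)
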