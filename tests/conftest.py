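import numpy as np
import pytest

from rtarch import genome_model as gm
from rtarch import timing as tm


@pytest.fixture(scope="session")
def default_sim():
    """Default synthetic genome (seed 1): sequences, truth, assays."""
    spec = gm.SyntheticGenomeSpec(seed=1)
    sequences, truth = gm.simulate_genome(spec)
    assays = gm.simulate_replication_assays(spec, truth)
    return spec, sequences, truth, assays


@pytest.fixture(scope="session")
def default_rt(default_sim):
    """RT and enrichment tracks computed from the default simulation."""
    spec, sequences, truth, assays = default_sim
    rt = {
        g: {
            c: tm.compute_rt(assays.early[g][c], assays.late[g][c])
            for c in sequences
        }
        for g in ("wt", "ko")
    }
    enr = {
        f: {
            c: tm.compute_rt(assays.chip[f][c], assays.chip_input[c])
            for c in sequences
        }
        for f in ("rif1", "laminB1")
    }
    return rt, enr


@pytest.fixture(scope="session")
def default_4c(default_sim):
    spec, sequences, truth, assays = default_sim
    libs = gm.simulate_4c_libraries(spec, truth, sequences)
    return libs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
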