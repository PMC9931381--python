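import numpy as np
import pytest

import manugrip as mg


@pytest.fixture(scope="session")
def default_study():
    """One default simulated study (54 subjects, 648 records), shared read-only."""
    return mg.simulate_study(mg.StudyDesign(seed=7))


@pytest.fixture(scope="session")
def default_pairs(default_study):
    return mg.build_pairs(default_study)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_loads(rng, total=300.0):
    """A valid random AreaLoads draw."""
    pct = rng.dirichlet(np.full(7, 5.0)) * 100.0
    return mg.AreaLoads.from_array(total, pct)
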