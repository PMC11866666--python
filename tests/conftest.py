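import numpy as np
import pytest

from pupilseed import synth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_spec():
    """Desk-scale cohort spec shared by integration-style tests."""
    return synth.CohortSpec(
        n_young=3,
        n_old=3,
        grid_shape=(8, 8, 4),
        n_volumes=80,
        plants=(synth.block_plant((1, 1, 1), (3, 2, 2), coupling_beta=0.8),),
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return synth.simulate_cohort(tiny_spec)
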