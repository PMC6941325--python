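import numpy as np
import pytest

from peptimark import SimulationConfig, simulate_cohort
from peptimark.pipeline import run_protease_pipeline


@pytest.fixture(scope="session")
def effect_cohort():
    """Small cohort with a 7-fold protease effect, shared across tests."""
    cfg = SimulationConfig(n_case=20, n_control=20, n_proteins=10,
                           protein_length=360, effects={"PR1": 7.0}, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def effect_pipeline(effect_cohort):
    c = effect_cohort
    return run_protease_pipeline(c.profiles, c.proteome, c.matrices,
                                 c.truth.labels, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
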