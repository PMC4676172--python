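import numpy as np
import pytest

from oltrecur.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A reduced cohort: 6 patients, 2 sequenced, moderate panel."""
    return SimulationConfig(
        seed=7,
        n_patients=6,
        n_recurrent=3,
        n_sequenced=2,
        planted_in_k=2,
        alpha=(0.4, 0.0),
        panel_size=500,
        n_genes=60,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def default_cohort():
    """The full study-design cohort at one seed."""
    return generate_cohort(SimulationConfig(seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
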