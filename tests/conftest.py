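import numpy as np
import pytest

from hccradiomics import SimulationConfig, build_default_catalog, simulate_cohort


@pytest.fixture(scope="session")
def catalog():
    return build_default_catalog()


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic study cohort: 38 patients, paired HT, planted effects."""
    return simulate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """Six-patient cohort for fast I/O round-trip tests."""
    return simulate_cohort(
        SimulationConfig(n_patients=6, grade_counts={"G1": 2, "G2": 2, "G3": 2}, seed=5)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
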