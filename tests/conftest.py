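import numpy as np
import pandas as pd
import pytest

from comorbnet.simulate import (SimulationConfig, generate_cohort,
                                synthetic_phecode_map)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_cases_per_stratum=60, control_pool_multiplier=4,
                            n_phenotypes=12, fraction_null=0.5, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def mini_map():
    return synthetic_phecode_map(12)


@pytest.fixture()
def toy_matrix():
    """Hand-built 4-patient, 3-phenotype incidence matrix."""
    return pd.DataFrame(
        [[1, 1, 0], [0, 0, 0], [1, 0, 1], [1, 1, 1]],
        index=pd.Index(["p1", "p2", "p3", "p4"], name="person_id"),
        columns=pd.Index(["P1", "P2", "P3"], name="phenotype"),
    ).astype(bool)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
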