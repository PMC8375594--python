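import numpy as np
import pytest

from mcinet import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """16-subject two-group cohort shared by feature/classification tests."""
    config = CohortConfig(n_per_group={"MCInc": 8, "MCIc": 8}, seed=42)
    return config, generate_cohort(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
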