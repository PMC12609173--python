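import numpy as np
import pytest

from cascnet.config import AnalysisConfig
from cascnet.simulate import simulate_study


@pytest.fixture(scope="session")
def small_study():
    """One modest synthetic study shared across read-only tests."""
    cohort, images, truth = simulate_study(n_patients=80, n_controls=20, seed=11)
    return cohort, images, truth


@pytest.fixture(scope="session")
def default_study():
    """Full-size default study (185 patients / 40 controls)."""
    cohort, images, truth = simulate_study(seed=3)
    return cohort, images, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def desk_config():
    return AnalysisConfig.desk_scale(n_perm=100)
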