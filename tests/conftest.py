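import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pahrisk import paper_like_scenario, run_paper_pipeline

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def scenario():
    return paper_like_scenario()


@pytest.fixture(scope="session")
def paper_run():
    """One full pipeline run on the packaged scenario at the study's
    iteration budget, shared across tests that inspect its outputs."""
    return run_paper_pipeline(seed=1, iterations=30_000)
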