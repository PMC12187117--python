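import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from ccta_cea import (  # noqa: E402
    default_distribution_specs,
    default_model_config,
    default_parameters,
    default_truth,
)


@pytest.fixture
def config():
    return default_model_config()


@pytest.fixture
def params():
    return default_parameters()


@pytest.fixture
def specs(params):
    return default_distribution_specs(params)


@pytest.fixture(scope="session")
def real_truth():
    return default_truth("real_world")


@pytest.fixture(scope="session")
def guideline_truth():
    return default_truth("guideline")
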