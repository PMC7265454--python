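import pytest
from hypothesis import HealthCheck, settings

import avatarlab as al
from avatarlab.metrics import experiment_table, integrated_factor

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def bank():
    return al.make_default_bank(seed=42)


@pytest.fixture(scope="session")
def default_dataset():
    """One full 17+15 x 6 experiment at the default study conditions."""
    return al.run_experiment(al.ExperimentConfig(seed=7))


@pytest.fixture(scope="session")
def metrics_table(default_dataset):
    return integrated_factor(experiment_table(default_dataset))
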