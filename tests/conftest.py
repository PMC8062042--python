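import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from airwaycrowd.io import PipelineConfig
from airwaycrowd.study import classify_results_table, measure_results_table
from airwaycrowd.synthetic import CohortConfig, CrowdConfig, simulate_study

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def sim_study():
    """Medium synthetic study: default mixture/noise, >=500 tasks.

    Shared session-wide; tests must not mutate it.
    """
    return simulate_study(
        seed=12345,
        cohort_config=CohortConfig(n_subjects=24, tasks_per_subject=(20, 26)),
    )


@pytest.fixture(scope="session")
def sim_labels(sim_study):
    return classify_results_table(sim_study["results"], PipelineConfig())


@pytest.fixture(scope="session")
def sim_measurements(sim_study, sim_labels):
    return measure_results_table(sim_study["results"], sim_labels, sim_study["frame"])


@pytest.fixture
def rng():
    return np.random.default_rng(987654321)
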