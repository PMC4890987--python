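import logging

import pytest

from genpnp import (
    SimulationConfig,
    emit_candidate_network,
    generate_ground_truth,
    simulate_cohort,
)

logging.getLogger("genpnp").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_nodes=30,
        n_mirnas=8,
        n_samples={"young": 30, "elderly": 60},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return generate_ground_truth(small_config)


@pytest.fixture(scope="session")
def small_candidates(small_truth):
    return emit_candidate_network(small_truth, 0.5, seed=101)


@pytest.fixture(scope="session")
def small_cohorts(small_truth):
    return {
        "young": simulate_cohort(small_truth, "young", 30, seed=201),
        "elderly": simulate_cohort(small_truth, "elderly", 60, seed=202),
    }
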