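"""Shared fixtures: tiny in-memory datasets and a small simulated screen."""

import numpy as np
import pytest

from kinresp import (
    ActivityMatrix,
    SimulationConfig,
    simulate_activity_matrix,
    simulate_screen,
)


@pytest.fixture
def tiny_profiles() -> ActivityMatrix:
    return ActivityMatrix(
        drug_ids=["D1", "D2", "D3"],
        kinase_ids=["K1", "K2"],
        values=np.array([[1.0, 0.2], [0.5, 0.0], [0.4, 1.0]]),
    )


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    # small but structured enough for end-to-end pipeline tests
    return SimulationConfig(
        n_drugs=30,
        n_kinases=40,
        targets_per_drug=5.0,
        n_active_kinases=4,
        true_beta_scale=0.6,
        noise_sd=0.05,
        pair_fraction=0.5,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    profiles = simulate_activity_matrix(small_config)
    screen, truth = simulate_screen(profiles, small_config)
    return profiles, screen, truth
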