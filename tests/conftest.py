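import numpy as np
import pytest

import casebase as cb


@pytest.fixture(scope="session")
def scenario1_model():
    """Single binary exposure: prevalence 0.3, OR 2.5, marginal risk 0.1."""
    return cb.solve_baseline_odds(
        [cb.CovariateSpec("x", "binary", prevalence=0.3)],
        {"x": np.log(2.5)}, 0.1)


@pytest.fixture(scope="session")
def scenario1_dataset(scenario1_model):
    """One fixed case-base draw from the standard design (N=1e5, gamma=0.05,
    tau=0.005)."""
    pop = cb.simulate_population(scenario1_model, 100_000, seed=8675309)
    return cb.draw_case_base_sample(
        pop, cb.SamplingDesign(100_000, 0.05, 0.005), seed=8675310)


@pytest.fixture
def hand_table():
    """Small worked example: recruited diseased 6 exposed / 4 unexposed,
    non-diseased base members 9 / 21, one diseased base member per arm
    (n_D = 10, n1 = 2, rho_hat = 0.2)."""
    return cb.BinaryCaseBaseTable(
        diseased_exposed=6, diseased_unexposed=4,
        base_exposed=10, base_unexposed=22,
        diseased_in_base_exposed=1, diseased_in_base_unexposed=1)


@pytest.fixture
def hand_dataset(hand_table):
    return cb.dataset_from_binary_table(hand_table)
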