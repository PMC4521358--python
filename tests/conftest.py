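import warnings

import pytest

import microdem as md


@pytest.fixture(scope="session")
def full_scenario():
    """The full-effects synthetic ground truth (seed fixed)."""
    return md.make_truth("full_effects", seed=1)


@pytest.fixture(scope="session")
def full_targets(full_scenario):
    """Noisy targets + initial state generated from the truth."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        targets, initial = md.generate_targets(full_scenario)
    return targets, initial


@pytest.fixture(scope="session")
def exact_targets(full_scenario):
    """Zero-noise targets: estimates equal the truth's outcomes."""
    targets, initial = md.generate_targets(full_scenario, noise_scale=0.0)
    return targets, initial


@pytest.fixture(scope="session")
def short_trajectory(full_scenario):
    """A 16-year expected-value run of the truth, shared across tests."""
    cfg = md.SimulationConfig(start_year=1992, end_year=2008)
    return md.simulate(full_scenario.params, full_scenario.initial_state, cfg), cfg

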