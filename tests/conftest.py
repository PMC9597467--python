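import pytest

from yamnue import biomass, calibration, synthetic_trial, uptake


@pytest.fixture(scope="session")
def default_config():
    return synthetic_trial.default_sim_config(seed=42)


@pytest.fixture(scope="session")
def sim_records(default_config):
    """One default simulated trial (144 plants), shared read-only."""
    return synthetic_trial.simulate_trial(default_config)


@pytest.fixture(scope="session")
def plant_frame(sim_records):
    """Per-plant traits + uptakes for the shared simulated trial."""
    traits = biomass.plant_traits(sim_records)
    up = uptake.uptake_frame(sim_records)
    return traits.merge(up, on=["genotype", "block", "treatment", "plant_id"])


@pytest.fixture(scope="session")
def trial_config():
    return calibration.DEFAULT_TRIAL_CONFIG


@pytest.fixture(scope="session")
def reference_means():
    return calibration.reference_means()
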