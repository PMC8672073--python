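"""Shared fixtures: small simulated datasets reused across test modules."""

import pytest

from lightpotential import SimConfig, derive_table, simulate_dataset, truth_frame


@pytest.fixture(scope="session")
def noiseless_dataset():
    """40 leaves rendered with zero noise: derive must invert exactly."""
    cfg = SimConfig(n_leaves=40, seed=7, noise_sd_fluor=0.0, noise_sd_ecs=0.0)
    measurements, truths = simulate_dataset(cfg)
    return cfg, measurements, truths


@pytest.fixture(scope="session")
def noiseless_table(noiseless_dataset):
    _, measurements, truths = noiseless_dataset
    return derive_table(measurements), truth_frame(truths)


@pytest.fixture(scope="session")
def default_dataset():
    """200 leaves at default noise with 10% planted pathologies."""
    cfg = SimConfig(n_leaves=200, seed=42, defect_frac=0.1)
    measurements, truths = simulate_dataset(cfg)
    return cfg, measurements, truths


@pytest.fixture(scope="session")
def default_table(default_dataset):
    _, measurements, truths = default_dataset
    return derive_table(measurements), truth_frame(truths)
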