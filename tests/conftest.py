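"""Shared fixtures: small plex designs and noise-free / noisy simulations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from secdeg.design import rotated_design
from secdeg.simulate import (
    SimConfig,
    generate_ground_truth,
    simulate_psm_tables,
)


@pytest.fixture(scope="session")
def designs21():
    return rotated_design(21)


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free generator settings: every downstream value is designed."""
    return SimConfig(
        n_proteins=10,
        n_cleavage_events=4,
        n_proteases_per_family=1,
        sigma_noise=0.0,
        missingness=0.0,
        low_purity_rate=0.0,
        decoy_rate=0.0,
        contaminant_rate=0.0,
    )


@pytest.fixture(scope="session")
def clean_truth(clean_config):
    return generate_ground_truth(clean_config, seed=11)


@pytest.fixture(scope="session")
def clean_sim(clean_truth, designs21):
    return simulate_psm_tables(clean_truth, designs21, seed=12)


@pytest.fixture(scope="session")
def clean_psms(clean_sim):
    return pd.concat(clean_sim.tables.values(), ignore_index=True)


@pytest.fixture(scope="session")
def noisy_config():
    """Default-like settings with noise, missingness, decoys and purity dropouts."""
    return SimConfig(n_proteins=14, n_cleavage_events=5)


@pytest.fixture(scope="session")
def noisy_truth(noisy_config):
    return generate_ground_truth(noisy_config, seed=21)


@pytest.fixture(scope="session")
def noisy_sim(noisy_truth, designs21):
    return simulate_psm_tables(noisy_truth, designs21, seed=22)


@pytest.fixture(scope="session")
def noisy_psms(noisy_sim):
    return pd.concat(noisy_sim.tables.values(), ignore_index=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
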