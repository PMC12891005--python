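"""Shared fixtures: small synthetic datasets and pre-run simulations.

Expensive artifacts (timelapses, trained estimators, long model runs) are
session-scoped so each is computed once per test session.
"""

from __future__ import annotations

import numpy as np
import pytest

import myconet as m


@pytest.fixture(scope="session")
def base_config() -> m.SyntheticRunConfig:
    return m.SyntheticRunConfig(seed=7)


@pytest.fixture(scope="session")
def timelapse_100h() -> m.SyntheticTimelapse:
    """100-h default-speed timelapse used across morphometry/flux tests."""
    return m.generate_timelapse(m.SyntheticRunConfig(seed=7, duration_h=100.0))


@pytest.fixture(scope="session")
def timelapse_200h() -> m.SyntheticTimelapse:
    """Full-duration timelapse for assay and calibration tests."""
    return m.generate_timelapse(m.SyntheticRunConfig(seed=11, duration_h=200.0))


@pytest.fixture(scope="session")
def clean_transects(base_config) -> "pd.DataFrame":
    """Noise-free transect dataset (no blur, illumination or label noise)."""
    return m.generate_transect_dataset(
        base_config.with_(transect_noise_sd=0.0),
        1500,
        label_noise_sd_um=0.0,
        augment_defocus=False,
        illumination_jitter=0.0,
        empty_fraction=0.05,
    )


@pytest.fixture(scope="session")
def noisy_transects(base_config) -> "pd.DataFrame":
    """Study-condition transect dataset (label noise 0.3 um, augmentation)."""
    return m.generate_transect_dataset(base_config, 1800)


@pytest.fixture(scope="session")
def clean_model(clean_transects) -> m.RadiusModel:
    train, _ = m.split_dataset(clean_transects, 0.9, seed=0)
    return m.train_estimator(train, seed=0)


@pytest.fixture(scope="session")
def noisy_split(noisy_transects):
    train, test = m.split_dataset(noisy_transects, 0.9, seed=0)
    return train, test


@pytest.fixture(scope="session")
def noisy_model(noisy_split) -> m.RadiusModel:
    return m.train_estimator(noisy_split[0], seed=0)


@pytest.fixture(scope="session")
def default_simulation() -> m.SimulationResult:
    """Default extended-model run: 900 h, feedback at the kappa0 setpoint."""
    return m.run_simulation(m.default_params(150.0, Rmax_mm=200.0), 900.0)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
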