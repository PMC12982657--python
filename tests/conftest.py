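"""Shared fixtures: synthetic worlds and toy hand-checkable inputs."""

from pathlib import Path

import pandas as pd
import pytest

from vlwkit import WorldSpec, generate_world

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def world():
    """Default 30-country noiseless synthetic world (seed 42)."""
    return generate_world(WorldSpec())


@pytest.fixture(scope="session")
def noisy_world():
    """Same world with observation noise on GDP, HALE and DALY series."""
    return generate_world(
        WorldSpec(seed=7, gdp_noise_sd=0.05, hale_noise_sd=1.0, daly_noise_sd=0.05)
    )


@pytest.fixture(scope="session")
def regional_table():
    """Published regional VLW / VLW-per-GDP estimates for 2021 (wide shape)."""
    return pd.read_csv(DATA_DIR / "regional_vlw_2021.csv")


@pytest.fixture()
def tiny_world():
    """Three countries in two regions; small enough for hand arithmetic."""
    return generate_world(WorldSpec(n_countries=3, n_regions=2, seed=11))
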