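import numpy as np
import pandas as pd
import pytest

from scoremr import SimConfig, SnpRecord, simulate_cohort, simulate_panel


@pytest.fixture
def toy_panel() -> list[SnpRecord]:
    """Three handcrafted instrument SNPs with easy weights."""
    return [
        SnpRecord("rs1", "A", "G", 0.30, 0.10, 0.01, 1e-9),
        SnpRecord("rs2", "C", "T", 0.50, 0.20, 0.01, 1e-9),
        SnpRecord("rs3", "G", "A", 0.70, 0.30, 0.01, 1e-9),
    ]


@pytest.fixture
def toy_dosages() -> pd.DataFrame:
    return pd.DataFrame(
        {"rs1": [2.0, 0.0], "rs2": [1.0, 0.0], "rs3": [0.0, 0.0]},
        index=["a", "b"],
    )


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_individuals=4000, n_cases_target=2000, seed=123)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    panel = simulate_panel(small_config)
    return panel, simulate_cohort(small_config, panel)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
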