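import numpy as np
import pandas as pd
import pytest

from dpscore import SimulationConfig
from dpscore.simulate import simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A compact full synthetic study shared by read-only tests."""
    cfg = SimulationConfig(n_subjects=150, n_variants=80, seed=11)
    return cfg, simulate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def toy_survival():
    """Hand-sized competing-risks table: death at 3, conversion at 6."""
    return pd.DataFrame({
        "subject_id": ["a", "b"],
        "time_months": [3.0, 6.0],
        "status": [2, 1],
        "carrier": [0, 1],
    })
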