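import numpy as np
import pytest

from longconn import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default cohort (30 CNT / 21 PD / 16 PROD, effect size 3)."""
    return simulate_cohort(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def train_split(default_cohort):
    """CNT+PD features and binary labels (PD = 1) of the default cohort."""
    tr = default_cohort.subset(["CNT", "PD"])
    y = (tr.labels == "PD").astype(int).to_numpy()
    return tr.features, y


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
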