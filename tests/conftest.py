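import numpy as np
import pytest

import stimnet as sn


@pytest.fixture(scope="session")
def small_study() -> sn.SyntheticStudy:
    """Compact synthetic study shared by read-only tests."""
    return sn.generate_study(
        n_electrodes=30, n_sites=1, n_trials=40, n_baseline_periods=10, seed=7
    )


@pytest.fixture(scope="session")
def layout20() -> sn.ElectrodeLayout:
    return sn.generate_layout(20, seed=3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
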