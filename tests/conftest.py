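import numpy as np
import pytest

from burdenmrf import SimConfig, generate_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dataset():
    """A modest fixed-number dataset shared by fast structural tests."""
    cfg = SimConfig(n_cases=300, n_controls=300, n_sites=30, n_causal=10,
                    group_par=0.05, seed=11)
    return generate_dataset(cfg, np.random.default_rng(11))


@pytest.fixture(scope="session")
def full_dataset():
    """One dataset at the study's reference scale (1000/1000 x 100)."""
    cfg = SimConfig(group_par=0.05, seed=7)
    return generate_dataset(cfg, np.random.default_rng(7))
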