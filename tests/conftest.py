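import numpy as np
import pytest

import dinmix as dm


@pytest.fixture(scope="session")
def table1_item():
    """The worked-example item: q = (1,1,1), g = s = 0.1, tau = (0.8, 0.1, 0.1)."""
    return dm.DinmixItemParams(0.1, 0.1, (0.8, 0.1, 0.1))


@pytest.fixture(scope="session")
def q111():
    return np.array([1, 1, 1])


@pytest.fixture(scope="session")
def small_dataset():
    """A small mixed-rule dataset with known truth for quick sampler runs."""
    design = dm.Study1Design(N=200, I=15, seed=42)
    return dm.simulate_study1(design)


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    cfg = dm.McmcConfig(chains=2, iterations=600, burn_in=300, seed=9)
    draws, summary = dm.fit(small_dataset.Y, small_dataset.Q, "dinmix", cfg)
    return small_dataset, draws, summary
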