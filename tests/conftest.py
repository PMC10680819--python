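import numpy as np
import pytest

import pivotdfe as pdfe

DEFAULT_SEED = 12345


@pytest.fixture(scope="session")
def default_dataset():
    """One default-configuration synthetic dataset shared across tests."""
    cfg = pdfe.GeneratorConfig(seed=DEFAULT_SEED)
    growth, effects, truth = pdfe.generate_dataset(cfg)
    return growth, effects, truth


@pytest.fixture(scope="session")
def default_fits(default_dataset):
    growth, effects, _ = default_dataset
    return pdfe.fit_all(effects, growth)


@pytest.fixture(scope="session")
def default_pivots(default_fits):
    return pdfe.estimate_pivots(default_fits.fits)


@pytest.fixture(scope="session")
def noise_free_dataset():
    """All noise terms switched off: effects are exactly b_m (lam - pivot)."""
    cfg = pdfe.GeneratorConfig(sigma_eta=0.0, sigma_xi=0.0, sigma_meas=0.0,
                               seed=DEFAULT_SEED)
    return pdfe.generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(DEFAULT_SEED)
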