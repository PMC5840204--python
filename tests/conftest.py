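import warnings

import numpy as np
import pytest

from oblfp.simulate import SimConfig, simulate_session


@pytest.fixture(autouse=True)
def _quiet_warnings():
    # small-n epochs trigger benign skip warnings in several analyses
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def small_session():
    """20-trial, 2-electrode session with a 6 dB beta contrast."""
    cfg = SimConfig(seed=7, n_trials=20, n_electrodes=2)
    cfg.band_effects["beta"].delta_db_splus = 6.0
    bundle, truth = simulate_session(cfg)
    return cfg, bundle, truth


@pytest.fixture(scope="session")
def null_session():
    """30-trial, 2-electrode session with no programmed effects."""
    cfg = SimConfig(seed=11, n_trials=30, n_electrodes=2)
    bundle, truth = simulate_session(cfg)
    return cfg, bundle, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
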