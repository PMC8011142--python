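import numpy as np
import pytest

import ethoclass as ec


@pytest.fixture(scope="session")
def stork_preset():
    """Back-mounted bird preset: config plus 4-behaviour specs."""
    return ec.preset("stork")


@pytest.fixture(scope="session")
def stork_bouts(stork_preset):
    """Small labelled bout sample: 25 bouts per behaviour, fixed seed."""
    cfg, specs = stork_preset
    return ec.generate_labelled_bouts(
        specs, n_per_class=25, bout_records=cfg.bout_len_records,
        fs=cfg.fs, seed=11,
    )


@pytest.fixture
def random_bout():
    """Factory for random bouts of arbitrary length."""

    def make(n=40, fs=10.54, seed=0, scale=1.0):
        rng = np.random.default_rng(seed)
        return ec.Bout(samples=rng.normal(0, scale, size=(n, 3)), fs=fs)

    return make
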