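import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def validation_study():
    """The end-to-end synthetic validation study: 10 noisy trials through
    the full marker-less pipeline (shared across acceptance tests)."""
    from stridehall.study import run_validation_study

    return run_validation_study(n_trials=10, seed=0, keep_trials=True)
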