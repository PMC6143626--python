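import numpy as np
import pytest

from acqcurves.engine import RuleConfig, run_batch


@pytest.fixture(scope="session")
def neutral_runs():
    """A small batch of neutral random-copy runs shared across tests."""
    return run_batch(
        RuleConfig("random_copy"), n_reps=40, base_seed=901, n=100, n_events=2000
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
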