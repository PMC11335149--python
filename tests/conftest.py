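import numpy as np
import pytest

from neurixn.data_model import make_pair_index
from neurixn.synthetic import GeneratorSpec, generate


@pytest.fixture(scope="session")
def pair_index():
    return make_pair_index()


@pytest.fixture(scope="session")
def tiny_trial_set():
    """One participant, 8 short trials — enough for split/window plumbing."""
    spec = GeneratorSpec(n_participants=1, n_trials=8, trial_seconds=10.0, seed=123)
    cohort, _ = generate(spec)
    return cohort[0]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
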