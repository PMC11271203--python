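import numpy as np
import pytest

from restcause import (
    dominant_source_truth,
    generate_var_timeseries,
)


@pytest.fixture(scope="session")
def small_dataset():
    """A 5-subject dataset with a known dominant source (component 1)."""
    truth = dominant_source_truth(4, coupling=0.4, subject_jitter_sd=0.0, seed=7)
    ts, gs = generate_var_timeseries(5, 300, 4, truth)
    return truth, ts, gs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
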