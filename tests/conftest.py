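import numpy as np
import pytest

from hrvbold import CohortSpec, NNIntervalSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_spec():
    """Small, fast cohort used across module tests."""
    return CohortSpec(n_subjects=12, seed=7, grid_dims=(6, 6, 6), n_volumes=120)


def random_nn_series(rng, n=200, mean_rr=900.0, sd=50.0, invalid_frac=0.0):
    """A random NN series with optional invalid intervals."""
    intervals = np.clip(rng.normal(mean_rr, sd, n), 300, None)
    onsets = np.concatenate([[0.0], np.cumsum(intervals[:-1]) / 1000.0])
    valid = rng.random(n) >= invalid_frac
    return NNIntervalSeries(onsets, intervals, valid)
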