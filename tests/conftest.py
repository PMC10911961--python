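import numpy as np
import pytest

import ternhmm as th


@pytest.fixture(scope="session")
def small_dataset():
    """3 tracks x 600 s in the default movement regime."""
    cfg = th.SimulationConfig(n_tracks=3, track_length_s=600)
    return th.make_dataset(cfg, seed=7)


@pytest.fixture(scope="session")
def small_series(small_dataset):
    return [th.track_to_steps(t) for t in small_dataset.tern_tracks]


@pytest.fixture(scope="session")
def small_fit(small_series):
    """Model 0 fit reused across tests that only need *a* converged fit."""
    return th.ForagingHMM(small_series, 0).fit(n_restarts=2, seed=3)


def random_hmm_instance(rng, n_states=2, tmax=8):
    """Random small HMM instance (delta, gammas, densities) for oracle checks."""
    T = int(rng.integers(2, tmax + 1))
    delta = rng.dirichlet(np.ones(n_states))
    gammas = rng.dirichlet(np.ones(n_states), size=(T - 1, n_states))
    b = rng.uniform(0.05, 3.0, size=(T, n_states))
    return delta, gammas, b
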