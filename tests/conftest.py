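import numpy as np
import pytest

import popglm as pg


@pytest.fixture(scope="session")
def small_truth():
    """Known 3-unit population model with one strong excitatory coupling."""
    return pg.make_ground_truth_population(
        3, seed=11, coupling_pairs=[(0, 1)], coupling_amp=0.4,
        coupling_sign_prob=1.0, coupling_tau_range_ms=(30.0, 60.0))


@pytest.fixture(scope="session")
def small_session(small_truth):
    trials = pg.generate_compact_trials(40, seed=12)
    sess = pg.simulate_population(small_truth, trials, seed=13)
    sess.validate()
    return sess


@pytest.fixture(scope="session")
def small_binned(small_session):
    return pg.bin_spikes(small_session)


@pytest.fixture(scope="session")
def hist_basis():
    return pg.make_raised_cosine_basis(10, 250.0, lag0_inclusive=False)


@pytest.fixture(scope="session")
def task_basis():
    return pg.make_raised_cosine_basis(8, 800.0, warp_offset=30.0,
                                       lag0_inclusive=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
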