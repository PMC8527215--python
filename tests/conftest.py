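import numpy as np
import pytest

from mavc.revealed_preference import ObservationSet


@pytest.fixture
def rng():
    return np.random.default_rng(20210308)


@pytest.fixture
def two_obs_cycle():
    """The canonical two-observation GARP-violating set.

    Observation 1 buys only Y at prices (1, 3); observation 2 buys only X at
    prices (3, 1).  Each chosen bundle costs 100/3 at the other observation's
    prices, so each is strictly cheaper than the bundle it was rejected for:
    a two-cycle of strict revealed preferences.
    """
    return ObservationSet(
        bundles=np.array([[0.0, 100.0 / 3.0], [100.0 / 3.0, 0.0]]),
        prices=np.array([[1.0, 3.0], [3.0, 1.0]]),
        budgets=np.array([100.0, 100.0]),
    )


def random_chooser_obs(rng, n_trials):
    """ObservationSet from a fresh uniform-random chooser block."""
    from mavc.synthetic_data import ChooserSpec, simulate_chooser_block

    block = simulate_chooser_block(
        rng, ChooserSpec(kind="random"), t=float(rng.uniform(0, 30)),
        n_trials=n_trials,
    )
    return ObservationSet.from_block(block)
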