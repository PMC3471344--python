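import numpy as np
import pytest

from fractorun import (
    DeletionModel,
    SimConfig,
    run_simulation,
    replay,
    table1_pair,
)


@pytest.fixture(scope="session")
def table1_result():
    """Replay of the five-event worked example on the 16-gene interval."""
    pair, script = table1_pair()
    return replay(pair, script)


@pytest.fixture(scope="session")
def sim_mu6(
):
    """One medium trajectory (mu=6, phi=0.75) shared across tests."""
    cfg = SimConfig(
        length=50_000,
        model=DeletionModel(mu=6.0, phi=0.75),
        seed=314,
        stop_theta=0.3,
        checkpoints=[0.9, 0.7, 0.5],
    )
    return run_simulation(cfg)


def random_pair_arrays(rng: np.random.Generator, n: int):
    """A random consolidated pattern respecting g + h >= 1."""
    state = rng.integers(0, 3, size=n)  # 0: duplicate, 1: deleted on G, 2: on H
    g = np.where(state == 1, 0, 1).astype(np.int8)
    h = np.where(state == 2, 0, 1).astype(np.int8)
    return g, h
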