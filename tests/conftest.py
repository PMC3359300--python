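import numpy as np
import pytest

from dynloop import LatticeConfig, init_random_chain
from dynloop.engine import ConformationEnsemble, Snapshot

NO_BONDS = np.empty((0, 3), dtype=np.int64)


@pytest.fixture
def rng():
    return np.random.default_rng(123)


@pytest.fixture
def small_config():
    return LatticeConfig(L=32)


@pytest.fixture
def small_chain(small_config):
    return init_random_chain(30, small_config, seed=5)


def make_ensemble(conformations, bonds=None, start_mcs=10, spacing=10):
    """Build an ensemble directly from coordinate arrays (for observable tests)."""
    snaps = []
    for k, pos in enumerate(conformations):
        b = NO_BONDS if bonds is None else np.asarray(bonds[k], dtype=np.int64).reshape(-1, 3)
        snaps.append(
            Snapshot(
                mcs=start_mcs + k * spacing,
                positions=np.asarray(pos),
                bonds=b,
            )
        )
    return ConformationEnsemble(snapshots=snaps)


@pytest.fixture
def straight_rod_ensemble():
    """Two identical straight-rod conformations at unit spacing along x."""
    n = 20
    pos = np.zeros((n, 3), dtype=np.int64)
    pos[:, 0] = np.arange(n)
    return make_ensemble([pos, pos.copy()])
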