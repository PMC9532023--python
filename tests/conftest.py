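import numpy as np
import pytest

import tadsim as ts
from tadsim.builder import make_fixture


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def dimer():
    return make_fixture("dimer_z")


@pytest.fixture(scope="session")
def two_phase_slab():
    return make_fixture("two_phase_slab")


@pytest.fixture(scope="session")
def uniform_mix():
    return make_fixture("uniform_mix")


@pytest.fixture(scope="session")
def hard_dimer_samples():
    """Bond lengths sampled from a long hard-dimer run (shared oracle)."""
    snap = make_fixture("dimer_z")
    params = ts.RunParams(dt=0.4, n_steps=120_000, sample_interval=40, seed=71)
    traj = ts.run(snap, params)
    r = np.array([
        np.linalg.norm(f.minimum_image(f.positions[0] - f.positions[1]))
        for f in traj.frames[50:]
    ])
    return r


@pytest.fixture(scope="session")
def soft_dimer_samples():
    """Bond lengths sampled from a long soft-dimer (WCA+FENE) run."""
    snap = make_fixture("dimer_z")
    params = ts.RunParams(dt=0.4, n_steps=120_000, sample_interval=40, seed=72,
                          mode="soft")
    traj = ts.run(snap, params)
    r = np.array([
        np.linalg.norm(f.minimum_image(f.positions[0] - f.positions[1]))
        for f in traj.frames[50:]
    ])
    return r
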