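import numpy as np
import pytest

from chromosteer.engine import RunParams, pushoff_relax
from chromosteer.polymer import (
    ForceFieldParams,
    box_side_for_volume_fraction,
    build_mitotic,
    maxwell_boltzmann_velocities,
    place_chains,
)


@pytest.fixture(scope="session")
def ff():
    return ForceFieldParams()


@pytest.fixture(scope="session")
def small_relaxed_system(ff):
    """2 x 100-bead mitotic system after push-off; session-cached.

    Tests must copy() before mutating.
    """
    n_beads, n_chains = 100, 2
    box = box_side_for_volume_fraction(n_beads * n_chains)
    confs = [build_mitotic(n_beads, loop_length_beads=12)
             for _ in range(n_chains)]
    state = place_chains(confs, box, seed=0)
    rng = np.random.default_rng(1)
    state.vel = maxwell_boltzmann_velocities(state.n_beads, 1.0, rng)
    pushoff_relax(state, ff, n_steps=2000,
                  run=RunParams(dt=0.005, friction=1.0, seed=2))
    return state


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
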