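import numpy as np
import pytest

from annealdock.fixtures import make_planted_minimum_instance
from annealdock.ligand_model import default_ligand
from annealdock.sa_engine import SAConfig

# Annealing schedule used on the coarse (3 Å) fixture lattices.  Moves of
# one node (3 Å) match the physical move scale of the production protocol
# (6 x 0.4 Å = 2.4 Å); the level count bounds the schedule because the
# sub-1% acceptance stop cannot fire when the always-accepted null move
# alone has probability (2·1+1)⁻³ = 3.7% — see docs/methods.md.
FIXTURE_SA = dict(
    max_displacement=1,
    cooling_factor=0.85,
    max_levels=45,
    level_max_moves=5000,
    level_max_accepted=500,
)


def fixture_sa_config(seed: int) -> SAConfig:
    return SAConfig(seed=seed, **FIXTURE_SA)


@pytest.fixture(scope="session")
def ligand():
    return default_ligand()


@pytest.fixture(scope="session")
def planted_instance():
    """One shared planted-minimum instance (3 Å lattice, paired wells)."""
    return make_planted_minimum_instance(seed=1)


@pytest.fixture(scope="session")
def c2_instance():
    """A planted instance made exactly C2-symmetric about the z axis."""
    return make_planted_minimum_instance(seed=7, c2_mirror=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
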