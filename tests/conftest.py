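"""Shared fixtures: the default CT ramp and a small low-energy slab database
used by the transport-level unit tests (built once per session)."""

import numpy as np
import pytest

from pmmc import CTRamp
from pmmc.database import build_database
from pmmc.geometry import VoxelGrid


@pytest.fixture(scope="session")
def ramp():
    return CTRamp.default()


@pytest.fixture(scope="session")
def small_db(ramp):
    """Slab database covering 10-40 MeV, enough for 30 MeV test beams."""
    return build_database(ramp, energy_grid=(10.0, 20.0, 30.0, 40.0),
                          n_per_record=4000, seed=7)


@pytest.fixture
def muscle_grid():
    """Homogeneous muscle block, 8 x 8 x 6 cm, 1 mm depth resolution."""
    hu = np.full((40, 40, 60), 40, dtype=np.int16)
    return VoxelGrid(hu=hu, spacing=(0.2, 0.2, 0.1), origin=(-4.0, -4.0, 0.0))
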