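import numpy as np
import pytest

from gardenflow.grid import GridTransform
from gardenflow.resistance import ResistanceSurface
from gardenflow.scenario import ScenarioConfig

TRANSFORM = GridTransform(0.0, 0.0, 10.0)


def make_surface(values, mask=None, cell=10.0) -> ResistanceSurface:
    """Resistance surface from a literal 2-D array (cell size in metres)."""
    values = np.asarray(values, dtype=float)
    return ResistanceSurface(values, GridTransform(0.0, 0.0, cell), mask)


@pytest.fixture
def small_config() -> ScenarioConfig:
    """A desk-scale scenario used across module tests."""
    return ScenarioConfig(
        grid_shape=(60, 60), n_blockgroups=50, n_gardens=8, seed=3
    )


@pytest.fixture
def blockgroups_2000():
    """Large block-group table for variable-recovery tests (one seed)."""
    from gardenflow.scenario import generate_blockgroups

    return generate_blockgroups(ScenarioConfig(n_blockgroups=2000, seed=11))
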