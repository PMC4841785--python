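import numpy as np
import pytest

from gridfield.arena import ArenaConfig
from gridfield.place import PlaceEnsemble


@pytest.fixture(scope="session")
def small_arena():
    """Periodic 40x40 arena, 20-pixel raster: cheap but resolvable."""
    return ArenaConfig(side_length=40.0, boundary="periodic", grid_resolution=20)


@pytest.fixture(scope="session")
def small_dog_ensemble(small_arena):
    """5x5 difference-of-Gaussians cells tiling the small arena."""
    return PlaceEnsemble.tiled(small_arena, cells_per_side=5, kind="dog",
                               sigma1=2.0, sigma2=4.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
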