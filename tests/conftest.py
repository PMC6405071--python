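import numpy as np
import pytest

from mdshape import ExperimentConfig, HyperCube, RFParams
from mdshape.synthetic import SceneSpec, make_scene


@pytest.fixture(scope="session")
def small_scene():
    """24x24 four-class scene with a confusable pair; fast enough for units."""
    return make_scene(SceneSpec(rows=24, cols=24, fields=(4, 4), seed=1))


@pytest.fixture(scope="session")
def small_cube(small_scene):
    return small_scene[0]


@pytest.fixture(scope="session")
def default_scene():
    """The full default 64x64x100 study scene."""
    return make_scene(SceneSpec(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def fast_config():
    """Experiment config with a light random forest, for pipeline tests."""
    return ExperimentConfig(
        rf=RFParams(n_trees=60, n_permutations=3, importance_max_samples=128),
        seed=0,
    )


def random_cube(rng, bands=12, rows=5, cols=4, wl_lo=400.0, wl_hi=900.0):
    data = rng.uniform(0.0, 1.0, size=(bands, rows, cols))
    wl = np.linspace(wl_lo, wl_hi, bands)
    return HyperCube(data, wl)
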