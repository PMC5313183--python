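import numpy as np
import pytest

from burnprob.grids import LandscapeGrid
from burnprob.synth import SynthConfig, generate_world


def make_uniform_landscape(nrows=20, ncols=20, cell_size=200.0,
                           fuel="pine", slope=0.0, burnable=None,
                           **overrides):
    """Flat, homogeneous landscape for targeted spread/sampling tests."""
    shape = (nrows, ncols)
    props = {f"prop_{name}": np.zeros(shape)
             for name in ("pine", "fir", "broadleaf", "others")}
    props[f"prop_{fuel}"] = np.ones(shape)
    layers = dict(
        cell_size=cell_size,
        dominant_age=np.full(shape, 18.0),
        elevation=np.zeros(shape),
        slope=np.full(shape, float(slope)),
        aspect=np.zeros(shape),
        pop_density=np.full(shape, 50.0),
        dist_road=np.ones(shape),
        dist_settlement=np.ones(shape),
        flat=np.ones(shape, dtype=bool),
        burnable=burnable,
        **props,
    )
    layers.update(overrides)
    return LandscapeGrid(**layers)


@pytest.fixture(scope="session")
def small_config():
    """A compact synthetic world: quick to generate, still structured."""
    return SynthConfig(seed=7, years=10, n_rows=48, n_cols=48)


@pytest.fixture(scope="session")
def small_world(small_config):
    return generate_world(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
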