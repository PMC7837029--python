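import numpy as np
import pytest

from heteroduo.simulate import IhcSimParams, PetSimParams, gen_pet_lesion


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_ihc_params():
    """Slide small enough for fast tests: 6x6 tiles of 32 px."""
    return IhcSimParams(grid_shape=(6, 6), tile_px=32, seed=7)


@pytest.fixture
def small_lesion():
    vol, voi, truth = gen_pet_lesion(
        PetSimParams(semi_axes_mm=(7.0, 6.0, 6.0), seed=11)
    )
    return vol, voi, truth


def random_normalized_symmetric(rng: np.random.Generator, levels: int) -> np.ndarray:
    m = rng.random((levels, levels))
    m = m + m.T
    return m / m.sum()
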