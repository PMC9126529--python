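import numpy as np
import pytest

from cytoprs.simulate import SimulationParams, render_tile, small_cohort_params


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_params():
    return small_cohort_params(6, seed=3)


@pytest.fixture(scope="session")
def rendered_tile(tiny_params):
    return render_tile(tiny_params, 0.5, np.random.default_rng(7))


@pytest.fixture(scope="session")
def default_params_small_tile():
    """Full default parameterization at a test-friendly tile size."""
    return SimulationParams(n_patients=4, tile_px=256, blasts_per_tile_range=(4, 6),
                            other_wbc_per_tile_range=(2, 4), rbc_per_tile_range=(4, 8), seed=9)


def disc_mask(radius: int, pad: int = 6) -> np.ndarray:
    n = 2 * (radius + pad) + 1
    yy, xx = np.mgrid[:n, :n]
    c = radius + pad
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2
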