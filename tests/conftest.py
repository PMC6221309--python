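import numpy as np
import pandas as pd
import pytest

from osteotex.heightmap import HeightMap
from osteotex.synthesis import (
    WearParams,
    build_registry,
    simulate_observation_table,
)
from osteotex.model import TextureMixedModel


@pytest.fixture(scope="session")
def registry():
    return build_registry()


@pytest.fixture(scope="session")
def observation_table(registry):
    return simulate_observation_table(registry, WearParams(), seed=42)


@pytest.fixture(scope="session")
def small_table(observation_table) -> pd.DataFrame:
    return observation_table.sample(n=150, random_state=0).reset_index(drop=True)


@pytest.fixture(scope="session")
def fitted_small(small_table) -> TextureMixedModel:
    """One short shared fit reused by the model summary tests."""
    return TextureMixedModel(chains=2, warmup=200, draws=150, seed=5).fit(small_table)


@pytest.fixture()
def sinusoid_surface() -> HeightMap:
    """Unit-amplitude sinusoid along x, λ = 100 µm, densely sampled."""
    n, ny, dx = 2048, 256, 1.5625
    x = np.arange(n) * dx
    z = np.sin(2 * np.pi * x / 100.0)[None, :].repeat(ny, 0)
    return HeightMap.from_array(z, dx=dx)


@pytest.fixture()
def smooth_noisy_surface() -> HeightMap:
    """Smooth deterministic texture with bounded uniform noise."""
    rng = np.random.default_rng(7)
    n = 64
    yy, xx = np.mgrid[0:n, 0:n] * 1.0
    z = np.sin(2 * np.pi * xx / 50) + 0.3 * rng.uniform(-1, 1, size=(n, n))
    return HeightMap.from_array(z, dx=1.0)


def random_rough_surface(seed: int, n: int = 64, with_mask: bool = False) -> HeightMap:
    """Band-limited random roughness used for oracle-equivalence checks."""
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    z = ndimage.gaussian_filter(rng.standard_normal((n, n)), 2.0, mode="wrap")
    z = z / z.std() + 0.02 * rng.standard_normal((n, n))
    if with_mask:
        holes = rng.random((n, n)) < 0.01
        z = np.where(holes, np.nan, z)
    return HeightMap.from_array(z, dx=1.0)
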