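import numpy as np
import pytest

from spotcount import ImageStack, SimulationConfig, simulate_stack


def gaussian_patch(amplitude, dy, dx, sigma, offset, side=7):
    """Noiseless isotropic 2D Gaussian patch, the fitter's generating model."""
    half = side // 2
    yy, xx = np.meshgrid(
        np.arange(-half, half + 1, dtype=float),
        np.arange(-half, half + 1, dtype=float),
        indexing="ij",
    )
    r2 = (yy - dy) ** 2 + (xx - dx) ** 2
    return amplitude * np.exp(-r2 / (2.0 * sigma**2)) + offset


@pytest.fixture
def patch_factory():
    return gaussian_patch


@pytest.fixture
def small_sim():
    """A small, quick synthetic stack with its ground truth (seeded)."""
    cfg = SimulationConfig(shape=(12, 96, 96), n_spots=12, seed=42, stack_id="small")
    return simulate_stack(cfg) + (cfg,)


@pytest.fixture
def flat_stack():
    return ImageStack(voxels=np.full((4, 32, 32), 50.0), stack_id="flat")
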