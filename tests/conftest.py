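import warnings

import numpy as np
import pytest

from choromorph import VoxelSpacing
from choromorph.phantom import make_slab_choroid, render_tubes, straight_tube


@pytest.fixture
def spacing():
    return VoxelSpacing(0.012, 3.0 / 256.0, 0.012)


@pytest.fixture
def iso_spacing():
    return VoxelSpacing(0.012, 0.012, 0.012)


@pytest.fixture
def small_slab(spacing):
    """64x48x64 slab choroid mask (0.7 of the depth range)."""
    shape = (64, 48, 64)
    ny_mm = shape[1] * spacing.dy
    return make_slab_choroid(shape, spacing, upper_depth=0.15 * ny_mm, thickness=0.7 * ny_mm)


@pytest.fixture
def tube_phantom(spacing, small_slab):
    """Small single-tube phantom (through-tube along x) with truth."""
    shape = small_slab.mask.shape
    ny_mm = shape[1] * spacing.dy
    ext_x = shape[0] * spacing.dx
    zc = shape[2] * spacing.dz / 2
    tube = straight_tube((0.0, ny_mm / 2, zc), (ext_x, ny_mm / 2, zc), 0.05)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        grid, truth = render_tubes([tube], small_slab, noise_sigma=0.01, seed=11)
    return grid, small_slab, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
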