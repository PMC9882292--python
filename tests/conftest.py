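import numpy as np
import pytest

from vesselprox.core import Calibration, VesselMask
from vesselprox.proximity import compute_distance_field
from vesselprox.synthetic import SyntheticConfig, generate_scene


# Dense map: many fine tubes, short nearest-vessel distances.
DENSE_CFG = SyntheticConfig(shape=(200, 300), n_tubes=8, tube_steps=40, seed=11)
# Sparse map: few larger tubes, extravascular distances spanning several
# attraction length scales (λ well identified).
SPARSE_CFG = SyntheticConfig(
    shape=(200, 300), n_tubes=2, tube_steps=40, tube_radius=8.0, seed=12
)


@pytest.fixture(scope="session")
def dense_scene():
    return generate_scene(DENSE_CFG)


@pytest.fixture(scope="session")
def sparse_scene():
    return generate_scene(SPARSE_CFG)


@pytest.fixture(scope="session")
def dense_field(dense_scene):
    return compute_distance_field(dense_scene.mask, dense_scene.roi)


@pytest.fixture(scope="session")
def sparse_field(sparse_scene):
    return compute_distance_field(sparse_scene.mask, sparse_scene.roi)


def random_mask(shape, n_vessel, seed, pixel_size=1.0):
    """A mask with exactly n_vessel distinct vessel pixels at random positions."""
    rng = np.random.default_rng(seed)
    grid = np.zeros(shape, dtype=bool)
    flat = rng.choice(shape[0] * shape[1], size=n_vessel, replace=False)
    grid.ravel()[flat] = True
    return VesselMask(grid=grid, calibration=Calibration(pixel_size=pixel_size))


def brute_force_field(mask):
    """Exhaustive min-over-vessel-pixel-centres distance at every pixel (μm)."""
    s = mask.pixel_size
    h, w = mask.shape
    ii, jj = np.nonzero(mask.grid)
    centers = np.column_stack([(jj + 0.5) * s, (ii + 0.5) * s])
    xs, ys = np.meshgrid((np.arange(w) + 0.5) * s, (np.arange(h) + 0.5) * s)
    pts = np.column_stack([xs.ravel(), ys.ravel()])
    d = np.sqrt(((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)).min(axis=1)
    return d.reshape(h, w)


def brute_force_cell_distances(points_um, mask):
    """Exhaustive min distance from each μm point to every vessel pixel centre."""
    s = mask.pixel_size
    ii, jj = np.nonzero(mask.grid)
    centers = np.column_stack([(jj + 0.5) * s, (ii + 0.5) * s])
    pts = np.atleast_2d(points_um)
    return np.sqrt(((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)).min(axis=1)
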