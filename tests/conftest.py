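import numpy as np
import pytest

from hipshape import (FemurPhantomSpec, LabelVolume, SurfaceMesh,
                      extract_mesh, make_femur_volume)


@pytest.fixture(scope="session")
def femur_spec():
    return FemurPhantomSpec()


@pytest.fixture(scope="session")
def left_volume(femur_spec):
    return make_femur_volume(femur_spec, "left")


@pytest.fixture(scope="session")
def left_mesh(left_volume):
    return extract_mesh(left_volume)


@pytest.fixture(scope="session")
def sphere_volume():
    """A 22 mm sphere voxelized at 0.8 mm, centred at the world origin."""
    h, r = 0.8, 22.0
    n = int(np.ceil(2 * (r + 2 * h) / h))
    origin = -h * (n - 1) / 2
    ii, jj, kk = np.indices((n, n, n), sparse=True)
    x, y, z = (ii * h + origin), (jj * h + origin), (kk * h + origin)
    grid = (x**2 + y**2 + z**2 <= r**2).astype(np.uint8)
    return LabelVolume(grid, (h, h, h), (origin, origin, origin), "RAS")


@pytest.fixture(scope="session")
def sphere_mesh(sphere_volume):
    return extract_mesh(sphere_volume, smoothing_iters=0)


def random_blob(rng, shape=(14, 12, 10), n_seeds=4, iters=2,
                spacing=(1.0, 1.0, 1.0)) -> LabelVolume:
    """Small random connected-ish mask for metric oracle comparisons."""
    from scipy import ndimage

    grid = np.zeros(shape, dtype=bool)
    idx = rng.integers(0, np.array(shape), size=(n_seeds, 3))
    grid[tuple(idx.T)] = True
    structure = ndimage.generate_binary_structure(3, 1)
    for _ in range(iters):
        grid = ndimage.binary_dilation(grid, structure=structure)
    return LabelVolume(grid.astype(np.uint8), spacing)
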