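import numpy as np
import pytest

from neurotau.io_core import BoldRun, Mask, VolumeGrid


@pytest.fixture
def small_grid():
    return VolumeGrid(shape=(4, 4, 4), affine=np.diag([2.0, 2.0, 2.0, 1.0]))


@pytest.fixture
def small_mask(small_grid):
    ind = np.zeros(small_grid.shape, dtype=bool)
    ind.ravel()[:10] = True
    return Mask(grid=small_grid, indicator=ind)


@pytest.fixture
def full_mask(small_grid):
    return Mask(grid=small_grid, indicator=np.ones(small_grid.shape, dtype=bool))


def make_mask(shape):
    grid = VolumeGrid(shape=shape, affine=np.diag([2.0, 2.0, 2.0, 1.0]))
    return Mask(grid=grid, indicator=np.ones(shape, dtype=bool))


def ar1_series(phi, T, rng, n=1, burn=100, sd=1.0):
    """Stationary AR(1) sample paths, shape (n, T)."""
    x = rng.normal(size=n) * sd / np.sqrt(1 - phi**2)
    out = np.empty((n, T))
    eps = rng.normal(scale=sd, size=(burn + T, n))
    for t in range(burn):
        x = phi * x + eps[t]
    for t in range(T):
        x = phi * x + eps[burn + t]
        out[:, t] = x
    return out


def make_run(data, mask, tr=2.0, subject_id="s1"):
    return BoldRun(subject_id=subject_id, data=np.asarray(data, float),
                   tr_seconds=tr, mask=mask)
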