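"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage


def thickness_oracle(phase: np.ndarray) -> np.ndarray:
    """Brute-force largest-inscribed-sphere local thickness (voxel units).

    For every foreground voxel p, try every foreground voxel c as a sphere
    centre: the sphere at c covers voxels strictly closer than the distance
    transform value dt(c), and its diameter is the voxel span along an
    axis, 2*(ceil(dt)-1)+1.  O(N^2); only usable on small grids, which is
    the point — it shares no code path with the production implementation.
    """
    dt = ndimage.distance_transform_edt(phase)
    centers = np.argwhere(phase)
    cdt = dt[phase]
    diam = 2.0 * (np.ceil(cdt) - 1.0) + 1.0
    d2max = np.round(cdt**2).astype(np.int64)
    out = np.full(phase.shape, np.nan)
    for p in np.argwhere(phase):
        d2 = ((centers - p) ** 2).sum(axis=1)
        covered = d2 < d2max
        out[tuple(p)] = diam[covered].max()
    return out


@pytest.fixture(scope="session")
def slab5() -> np.ndarray:
    a = np.zeros((12, 12, 12), dtype=bool)
    a[3:8] = True
    return a


@pytest.fixture(scope="session")
def ball11() -> np.ndarray:
    z, y, x = np.ogrid[:15, :15, :15]
    return (z - 7) ** 2 + (y - 7) ** 2 + (x - 7) ** 2 <= 25


@pytest.fixture(scope="session")
def random_blobs() -> list[np.ndarray]:
    """Small random binary structures for exactness checks (<= 24^3)."""
    rng = np.random.default_rng(42)
    cases = []
    for sigma in (1.5, 2.0, 2.5):
        f = ndimage.gaussian_filter(rng.standard_normal((22, 22, 22)), sigma)
        cases.append(f > np.quantile(f, 0.7))
    for _ in range(2):
        cases.append(rng.random((10, 10, 10)) > 0.5)
    return [c for c in cases if c.any()]
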