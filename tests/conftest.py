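"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from tractoprof import VolumeGrid


@pytest.fixture
def unit_grid() -> VolumeGrid:
    """20^3 grid, 1 mm isotropic, identity affine."""
    return VolumeGrid(shape=(20, 20, 20), affine=np.eye(4))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def voxels_bruteforce(streamline: np.ndarray, grid: VolumeGrid, step_mm: float = 0.01):
    """Dense-sampling voxel membership oracle, independent of the library path.

    Samples every segment at ``step_mm`` spacing and assigns samples to
    voxels with the voxel-centre rounding convention.
    """
    pts = np.asarray(streamline, dtype=float)
    inv = np.linalg.inv(grid.affine)
    samples = [pts[0]]
    for a, b in zip(pts[:-1], pts[1:]):
        length = np.linalg.norm(b - a)
        n = max(int(np.ceil(length / step_mm)), 1)
        t = np.arange(1, n + 1) / n
        samples.append(a + t[:, None] * (b - a))
    dense = np.vstack([np.atleast_2d(s) for s in samples])
    vox = np.rint(dense @ inv[:3, :3].T + inv[:3, 3]).astype(int)
    keep = np.all((vox >= 0) & (vox < np.array(grid.shape)), axis=1)
    return set(map(tuple, vox[keep]))


def random_polyline(rng: np.random.Generator, n_points: int = 12, scale: float = 15.0,
                    origin: float = 2.0) -> np.ndarray:
    """A smooth-ish random polyline inside a ~20 mm box."""
    start = origin + rng.uniform(0, scale, 3)
    steps = rng.normal(0, 1.2, (n_points - 1, 3))
    pts = np.vstack([start, start + np.cumsum(steps, axis=0)])
    # clip bounds deliberately off the half-integer rounding boundaries
    return np.clip(pts, 0.6, origin + scale + 1.9).astype(np.float32)
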