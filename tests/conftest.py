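"""Shared fixtures: small grids, random proper masks, brute-force oracles.

The oracles deliberately use all-pairs voxel-center arithmetic (O(n^2)) so
they stay independent of the scipy-based implementations they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from atlasfuse import BinaryMask, GridGeometry


@pytest.fixture
def unit_grid() -> GridGeometry:
    return GridGeometry(shape=(5, 5, 5))


@pytest.fixture
def aniso_grid() -> GridGeometry:
    return GridGeometry(shape=(6, 6, 6), spacing=(1.0, 1.0, 2.0))


def random_proper_mask(rng: np.random.Generator, geometry: GridGeometry, p: float = 0.4) -> BinaryMask:
    """A random mask that is neither empty nor all-foreground."""
    while True:
        m = rng.random(geometry.shape) < p
        if m.any() and not m.all():
            return BinaryMask(geometry, m)


def brute_force_signed_distance(mask: BinaryMask) -> np.ndarray:
    """All-pairs voxel-center signed Euclidean distance in mm."""
    geom = mask.geometry
    coords = np.array(
        list(itertools.product(*[range(n) for n in geom.shape])), dtype=float
    ) * np.array(geom.spacing)
    flat = mask.membership.ravel()
    fg, bg = coords[flat], coords[~flat]
    out = np.empty(flat.shape, dtype=float)
    for i, c in enumerate(coords):
        if flat[i]:
            out[i] = -np.sqrt(((bg - c) ** 2).sum(axis=1)).min()
        else:
            out[i] = np.sqrt(((fg - c) ** 2).sum(axis=1)).min()
    return out.reshape(geom.shape)


def brute_force_dilate(mask: BinaryMask, margin_mm: float) -> np.ndarray:
    """All-pairs voxel-center dilation by a physical margin."""
    geom = mask.geometry
    coords = np.array(
        list(itertools.product(*[range(n) for n in geom.shape])), dtype=float
    ) * np.array(geom.spacing)
    fg = coords[mask.membership.ravel()]
    out = np.array(
        [np.sqrt(((fg - c) ** 2).sum(axis=1)).min() <= margin_mm for c in coords]
    )
    return out.reshape(geom.shape)


def ball_mask(geometry: GridGeometry, center_mm: tuple, radius_mm: float) -> BinaryMask:
    zz, yy, xx = geometry.voxel_centers()
    c0, c1, c2 = center_mm
    return BinaryMask(
        geometry, (zz - c0) ** 2 + (yy - c1) ** 2 + (xx - c2) ** 2 <= radius_mm**2
    )
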