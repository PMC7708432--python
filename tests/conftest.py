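"""Shared fixtures: small grids, canonical cells, and a grown colony.

Everything is generated programmatically at test time; the expensive
fixtures (grown colonies, rendered volumes) are session-scoped so the whole
suite pays for them once.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from biofilm3d.arrangement import (
    CellArrangement,
    GridSpec,
    InstanceMap,
    SPECIES_PRESETS,
    calibrate_density,
    grow_biofilm,
    rasterize_instances,
)
from biofilm3d.geometry import Spherocylinder


@pytest.fixture(scope="session")
def grid_small() -> GridSpec:
    return GridSpec((40, 40, 80), (0.1, 0.1, 0.1))


@pytest.fixture(scope="session")
def single_rod(grid_small):
    """A 3 × 1 µm rod along x, plus its rasterized mask."""
    rod = Spherocylinder(1, (2.0, 2.0, 4.0), (0, 0, 1), 2.0, 1.0)
    mask = rasterize_instances(CellArrangement([rod]), grid_small).labels == 1
    return rod, mask


@pytest.fixture(scope="session")
def elbow_pair(grid_small):
    """Two rods meeting at a 90° elbow, rasterized into one fused mask."""
    rod_a = Spherocylinder(1, (2.0, 1.0, 2.0), (0, 1, 0), 2.0, 1.0)
    rod_b = Spherocylinder(2, (2.0, 2.6, 3.4), (0, 0, 1), 2.0, 1.0)
    arr = CellArrangement([rod_a, rod_b])
    inst = rasterize_instances(arr, grid_small)
    return arr, inst


def make_fused_pair(angle_deg: float, grid: GridSpec):
    """Truth (2 labels) and fused (1 label) maps for an end-to-end pair."""
    l, d = 2.0, 1.0
    a1 = np.array([0.0, 1.0, 0.0])
    c1 = np.array([2.0, 2.2, 3.0])
    tip = c1 + a1 * (l / 2)
    th = np.radians(angle_deg)
    a2 = np.array([0.0, np.cos(th), np.sin(th)])
    c2 = tip + a2 * (l / 2 + 0.35)  # slight overlap so the masks fuse
    arr = CellArrangement(
        [Spherocylinder(1, c1, a1, l, d), Spherocylinder(2, c2, a2, l, d)]
    )
    truth = rasterize_instances(arr, grid)
    fused = InstanceMap(
        (np.asarray(truth.labels) > 0).astype(np.uint16), grid
    )
    return truth, fused


@pytest.fixture(scope="session")
def fused_grid() -> GridSpec:
    return GridSpec((42, 70, 90), (0.1, 0.1, 0.1))


@pytest.fixture(scope="session")
def colony60():
    """A grown ~100-cell E. coli colony calibrated to 60% local density."""
    params = dataclasses.replace(SPECIES_PRESETS["e_coli"], max_cells=100)
    arr = grow_biofilm(params, seed=5)
    result = calibrate_density(arr, 0.60, tile_shape=(8, 32, 32))
    grid = GridSpec.from_bounds(
        result.arrangement.tight_bounds(), margin=0.8
    )
    inst = rasterize_instances(result.arrangement, grid)
    return result.arrangement, grid, inst, result.achieved_fraction


@pytest.fixture(scope="session")
def colony_sparse():
    """A small sparse colony (fast fixture for imaging round trips)."""
    params = dataclasses.replace(SPECIES_PRESETS["e_coli"], max_cells=40)
    arr = grow_biofilm(params, seed=11)
    result = calibrate_density(arr, 0.35, tile_shape=(8, 32, 32))
    grid = GridSpec.from_bounds(result.arrangement.tight_bounds(), margin=0.8)
    inst = rasterize_instances(result.arrangement, grid)
    return result.arrangement, grid, inst
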