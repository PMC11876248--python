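"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's vectorized/FFT code
paths: edge counting by explicit pair enumeration, kernel averaging by a
double loop over stencil offsets, and the full pipeline by cell-wise sums,
so agreement is meaningful.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from pollscape.grid import AGRICULTURE, HABITAT, LandscapeGrid


@pytest.fixture
def half_split_grid() -> LandscapeGrid:
    """2000x2000 m at 10 m cells, left half habitat (analytic LSI 1.25)."""
    values = np.full((200, 200), AGRICULTURE, dtype=np.int32)
    values[:, :100] = HABITAT
    return LandscapeGrid(values, cell_size=10.0)


@pytest.fixture
def checkerboard_grid() -> LandscapeGrid:
    """200x200 checkerboard at 10 m cells (analytic LSI 100.5)."""
    idx = np.indices((200, 200)).sum(axis=0)
    values = np.where(idx % 2 == 0, HABITAT, AGRICULTURE).astype(np.int32)
    return LandscapeGrid(values, cell_size=10.0)


def brute_force_edge_length(grid: LandscapeGrid) -> float:
    """Total edge length in metres by explicit 4-neighbour pair enumeration."""
    v = grid.values
    h = grid.cell_size
    total = 2.0 * (grid.nrows + grid.ncols) * h
    for i in range(grid.nrows):
        for j in range(grid.ncols):
            if j + 1 < grid.ncols and v[i, j] != v[i, j + 1]:
                total += h
            if i + 1 < grid.nrows and v[i, j] != v[i + 1, j]:
                total += h
    return total


def brute_force_lsi(grid: LandscapeGrid) -> float:
    return 0.25 * brute_force_edge_length(grid) / math.sqrt(grid.area)


def brute_force_kernel_average(
    field: np.ndarray, kernel: np.ndarray, boundary_mode: str
) -> np.ndarray:
    """Direct-sum kernel average, cell by cell."""
    nr, nc = field.shape
    kr, kc = kernel.shape
    ri, rj = kr // 2, kc // 2
    out = np.zeros_like(field, dtype=float)
    for i in range(nr):
        for j in range(nc):
            acc = 0.0
            wsum = 0.0
            for di in range(-ri, ri + 1):
                for dj in range(-rj, rj + 1):
                    w = kernel[di + ri, dj + rj]
                    if w == 0.0:
                        continue
                    ii, jj = i + di, j + dj
                    if boundary_mode == "torus":
                        acc += w * field[ii % nr, jj % nc]
                        wsum += w
                    elif 0 <= ii < nr and 0 <= jj < nc:
                        acc += w * field[ii, jj]
                        wsum += w
            if boundary_mode == "torus":
                out[i, j] = acc  # kernel already sums to 1
            else:
                out[i, j] = acc / wsum if wsum > 0 else 0.0
    return out


def brute_force_pipeline(
    values: np.ndarray,
    cell_size: float,
    hazard_by_code: dict[int, float],
    habitat_codes: set[int],
    kernel: np.ndarray,
    boundary_mode: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Independent exposure/health/service computation from first principles."""
    hazard = np.zeros(values.shape, dtype=float)
    for code, hz in hazard_by_code.items():
        hazard[values == code] = hz
    exposure = brute_force_kernel_average(hazard, kernel, boundary_mode)
    health = np.maximum(100.0 - exposure, 0.0)
    habitat = np.isin(values, list(habitat_codes))
    contribution = np.where(habitat, health, 0.0)
    service = brute_force_kernel_average(contribution, kernel, boundary_mode)
    return exposure, health, service
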