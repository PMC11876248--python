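"""Stylized multi-crop land-use scenario and the two-foraging-range runs.

The packaged layout is a synthetic, rectangular-parcel emulation of a Dutch
river-area fruit-growing landscape: a compact cluster of pesticide-treated,
pollination-demanding fruit parcels (75 % hazard) in one part of the
landscape, pesticide-free arable fields elsewhere, and four small habitat
patches — two directly adjacent to the fruit cluster and two embedded among
the pesticide-free fields, out of short-range foraging reach of the fruit
trees.  The model is run over the identical landscape for two foraging
ranges (400 m and 1000 m by default) to contrast short- and long-range
forager guilds.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import CROP_NOPEST, FRUIT, HABITAT, OTHER, FieldMap, LandscapeGrid
from .kernels import KernelSpec
from .model import ClassTable, ModelResult, run_model

__all__ = [
    "Parcel",
    "ScenarioSpec",
    "build_scenario_fixture",
    "default_scenario",
    "run_scenario",
    "habitat_patch_summary",
]

SCENARIO_CLASS_CODES = {
    "OTHER": OTHER,
    "HABITAT": HABITAT,
    "FRUIT": FRUIT,
    "CROP_NOPEST": CROP_NOPEST,
}


@dataclass(frozen=True)
class Parcel:
    """Axis-aligned rectangle in metres, lower-left (x0, y0) to upper-right (x1, y1)."""

    x0: float
    y0: float
    x1: float
    y1: float
    class_name: str

    def __post_init__(self) -> None:
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError("parcel must have positive width and height")
        if self.class_name not in SCENARIO_CLASS_CODES:
            raise ValueError(f"unknown parcel class {self.class_name!r}")


@dataclass(frozen=True)
class ScenarioSpec:
    extent: tuple[float, float] = (3000.0, 3000.0)
    cell_size: float = 10.0
    parcels: tuple[Parcel, ...] = ()
    fruit_hazard: float = 75.0
    foraging_ranges: tuple[float, ...] = (400.0, 1000.0)


def default_scenario() -> ScenarioSpec:
    """The packaged synthetic fixture layout (all coordinates in metres).

    West: a 1200 x 1800 m block of fruit parcels with two small habitat
    patches embedded inside it (surrounded by treated fruit trees); two more
    patches sit among pesticide-free fields ~900 m east of the cluster,
    beyond a 400 m foraging range but partly within a 1000 m one.  Thin
    OTHER strips emulate roads.
    """
    parcels = (
        Parcel(0, 0, 3000, 3000, "CROP_NOPEST"),
        # roads
        Parcel(0, 1480, 3000, 1500, "OTHER"),
        Parcel(1780, 0, 1800, 3000, "OTHER"),
        # fruit-parcel cluster
        Parcel(200, 600, 800, 2400, "FRUIT"),
        Parcel(800, 600, 1400, 1500, "FRUIT"),
        Parcel(800, 1500, 1400, 2400, "FRUIT"),
        # habitat patches surrounded by the fruit cluster
        Parcel(1000, 1900, 1100, 2000, "HABITAT"),
        Parcel(450, 900, 550, 1000, "HABITAT"),
        # habitat patches among pesticide-free fields
        Parcel(2300, 2200, 2400, 2300, "HABITAT"),
        Parcel(2350, 700, 2450, 800, "HABITAT"),
    )
    return ScenarioSpec(parcels=parcels)


def build_scenario_fixture(spec: ScenarioSpec) -> tuple[LandscapeGrid, ClassTable]:
    """Rasterize the parcel layout; later parcels overwrite earlier ones.

    The background class is OTHER.  A cell belongs to a parcel when its
    centre lies inside the rectangle.
    """
    width, height = spec.extent
    h = spec.cell_size
    ncols = int(round(width / h))
    nrows = int(round(height / h))
    values = np.full((nrows, ncols), OTHER, dtype=np.int32)
    xc = (np.arange(ncols) + 0.5) * h
    yc = (nrows - np.arange(nrows) - 0.5) * h  # row 0 is the top row
    for parcel in spec.parcels:
        if parcel.x0 < 0 or parcel.y0 < 0 or parcel.x1 > width or parcel.y1 > height:
            raise ValueError(f"parcel {parcel} extends outside the landscape extent")
        cols = (xc > parcel.x0) & (xc < parcel.x1)
        rows = (yc > parcel.y0) & (yc < parcel.y1)
        values[np.ix_(rows, cols)] = SCENARIO_CLASS_CODES[parcel.class_name]
    grid = LandscapeGrid(values, cell_size=h, class_codes=dict(SCENARIO_CLASS_CODES))
    return grid, ClassTable.scenario(spec.fruit_hazard)


def run_scenario(
    grid: LandscapeGrid,
    classes: ClassTable,
    ranges: Sequence[float],
    decay_length: float | None = None,
    boundary_mode: str = "renormalize",
) -> dict[float, ModelResult]:
    """One full model run per foraging range on the identical landscape.

    The kernel decay length scales with the range (delta = r/2) unless
    overridden.
    """
    out: dict[float, ModelResult] = {}
    for r in ranges:
        if r <= 0:
            raise ValueError("foraging ranges must be positive")
        delta = decay_length if decay_length is not None else r / 2.0
        spec = KernelSpec(r, delta, grid.cell_size, boundary_mode=boundary_mode)
        out[float(r)] = run_model(grid, classes, spec)
    return out


def habitat_patch_summary(
    health: FieldMap, grid: LandscapeGrid, classes: ClassTable
) -> pd.DataFrame:
    """Per-patch health summary for the habitat patches.

    Patches are 4-connected components of habitat cells.  ``dist_to_fruit``
    is the minimum centre-to-centre distance (m) from any patch cell to any
    fruit cell — used to separate fruit-adjacent from distant patches.
    """
    habitat = classes.habitat_mask(grid)
    labels, n_patches = ndimage.label(habitat, structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    fruit = grid.values == FRUIT
    if fruit.any():
        # distance from every cell to the nearest fruit cell, in metres
        dist = ndimage.distance_transform_edt(~fruit, sampling=grid.cell_size)
    else:
        dist = np.full(grid.values.shape, np.inf)
    rows = []
    for pid in range(1, n_patches + 1):
        cells = labels == pid
        rows.append(
            {
                "patch": pid,
                "n_cells": int(cells.sum()),
                "mean_health": float(health.values[cells].mean()),
                "dist_to_fruit": float(dist[cells].min()),
            }
        )
    return pd.DataFrame(rows).sort_values("dist_to_fruit", ignore_index=True)
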