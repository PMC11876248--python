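"""Raster containers shared by every stage of the model.

Conventions used throughout the package:

* regular square grids, row-major arrays, 0-based indices;
* the array row 0 is the *top* row of the map, the origin ``(x0, y0)`` is the
  lower-left corner of the landscape in metres;
* cell centres sit at ``(x0 + (j + 0.5) h, y0 + (nrows - i - 0.5) h)`` for
  cell size ``h``;
* all lengths are metres, all model quantities are percentages in [0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "LandscapeGrid",
    "FieldMap",
    "HABITAT",
    "AGRICULTURE",
    "FRUIT",
    "CROP_NOPEST",
    "OTHER",
    "BINARY_CODES",
    "GRID_NODATA",
    "FIELD_NODATA",
]

# class codes for the binary gradient landscapes
HABITAT = 1
AGRICULTURE = 2
# additional codes for the multi-crop scenario
FRUIT = 3
CROP_NOPEST = 4
OTHER = 0

BINARY_CODES: Mapping[str, int] = {"HABITAT": HABITAT, "AGRICULTURE": AGRICULTURE}

GRID_NODATA = -1
FIELD_NODATA = -9999.0


@dataclass
class LandscapeGrid:
    """Categorical land-use raster on a regular square grid."""

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    class_codes: Mapping[str, int] = field(default_factory=lambda: dict(BINARY_CODES))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("landscape grid must be a non-empty 2-D array")
        if not np.issubdtype(self.values.dtype, np.integer):
            raise TypeError("landscape grid values must be integer class codes")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        known = set(self.class_codes.values())
        present = set(np.unique(self.values).tolist())
        unknown = present - known
        if unknown:
            raise ValueError(f"grid contains codes not in class_codes: {sorted(unknown)}")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float]:
        """(width, height) of the landscape in metres."""
        return (self.ncols * self.cell_size, self.nrows * self.cell_size)

    @property
    def area(self) -> float:
        """Total landscape area in m^2."""
        return self.nrows * self.ncols * self.cell_size**2

    def class_mask(self, code: int) -> np.ndarray:
        return self.values == code

    def fraction(self, code: int) -> float:
        """Realized share of cells holding ``code``."""
        return float(np.count_nonzero(self.values == code)) / self.values.size


@dataclass
class FieldMap:
    """Continuous raster of one model quantity aligned to a LandscapeGrid.

    ``mask`` marks the cells where the quantity is defined; undefined cells
    carry :data:`FIELD_NODATA` when written to disk.
    """

    values: np.ndarray
    quantity: str
    cell_size: float
    mask: np.ndarray | None = None
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("field map must be a non-empty 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must match values shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def masked_values(self) -> np.ndarray:
        """Values on defined cells, 1-D."""
        return self.values[self.mask]

    def filled(self, fill: float = FIELD_NODATA) -> np.ndarray:
        out = self.values.copy()
        out[~self.mask] = fill
        return out

    def mean(self) -> float:
        """Arithmetic mean over defined cells; NaN if none are defined."""
        if not self.mask.any():
            return float("nan")
        return float(self.values[self.mask].mean())
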