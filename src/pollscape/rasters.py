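"""ESRI ASCII grid I/O for landscapes and field maps.

Categorical landscapes are written with integer values and nodata -1; field
maps with 6-decimal floats and nodata -9999.  Output is deterministic: the
same raster always serializes to identical bytes.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np

from .grid import BINARY_CODES, FIELD_NODATA, GRID_NODATA, FieldMap, LandscapeGrid

__all__ = ["RasterFormatError", "read_raster", "read_landscape", "read_field", "write_raster"]

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


class RasterFormatError(ValueError):
    """Malformed or truncated raster file."""


def _read_ascii(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise RasterFormatError(f"cannot read {path}: {exc}") from exc
    lines = text.splitlines()
    header: dict[str, float] = {}
    body_start = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS:
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError as exc:
                raise RasterFormatError(f"bad header line {line!r} in {path}") from exc
            body_start = i + 1
        else:
            break
    for key in ("ncols", "nrows"):
        if key not in header:
            raise RasterFormatError(f"missing {key} in header of {path}")
    if "cellsize" not in header:
        import warnings

        warnings.warn(f"{path}: no cellsize in header, assuming 1 m", stacklevel=3)
        header["cellsize"] = 1.0
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    tokens = " ".join(lines[body_start:]).split()
    if len(tokens) != nrows * ncols:
        raise RasterFormatError(
            f"{path}: expected {nrows * ncols} values, found {len(tokens)} (truncated file?)"
        )
    try:
        data = np.array(tokens, dtype=float).reshape(nrows, ncols)
    except ValueError as exc:
        raise RasterFormatError(f"{path}: non-numeric raster values") from exc
    header["_is_integer"] = float(all("." not in t and "e" not in t.lower() for t in tokens))
    return data, header


def read_landscape(
    path: str | Path, class_codes: Mapping[str, int] | None = None
) -> LandscapeGrid:
    """Read a categorical landscape raster (integer codes, nodata -1)."""
    data, header = _read_ascii(path)
    if not np.all(data == np.round(data)):
        raise RasterFormatError(f"{path}: non-integer values in a categorical raster")
    values = data.astype(np.int32)
    if class_codes is None:
        codes = {int(c) for c in np.unique(values) if c != GRID_NODATA}
        class_codes = {f"CLASS_{c}": c for c in sorted(codes)}
        for name, code in BINARY_CODES.items():
            if code in codes:
                class_codes[name] = code
                class_codes.pop(f"CLASS_{code}", None)
    return LandscapeGrid(
        values,
        cell_size=header["cellsize"],
        origin=(header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
        class_codes=class_codes,
    )


def read_field(path: str | Path, quantity: str = "field") -> FieldMap:
    """Read a continuous raster; nodata cells become masked-out."""
    data, header = _read_ascii(path)
    nodata = header.get("nodata_value", FIELD_NODATA)
    mask = data != nodata
    return FieldMap(
        data,
        quantity=quantity,
        cell_size=header["cellsize"],
        mask=mask,
        origin=(header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
    )


def read_raster(path: str | Path) -> LandscapeGrid | FieldMap:
    """Read a raster, dispatching on content: integer-valued -> categorical."""
    _, header = _read_ascii(path)
    if header["_is_integer"]:
        return read_landscape(path)
    return read_field(path)


def write_raster(
    obj: LandscapeGrid | FieldMap, path: str | Path, fmt: str | None = None
) -> Path:
    """Write a landscape or field map as an ESRI ASCII grid.

    ``fmt`` may force "int" or "float" encoding; a categorical landscape
    refuses the float encoding (and vice versa) to prevent silent type loss.
    """
    path = Path(path)
    if fmt is not None:
        expected = "int" if isinstance(obj, LandscapeGrid) else "float"
        if fmt != expected:
            raise TypeError(
                f"cannot write a {type(obj).__name__} with fmt={fmt!r}; use {expected!r}"
            )
    if isinstance(obj, LandscapeGrid):
        nodata = GRID_NODATA
        body = "\n".join(" ".join(str(int(v)) for v in row) for row in obj.values)
    elif isinstance(obj, FieldMap):
        nodata = FIELD_NODATA
        filled = obj.filled(FIELD_NODATA)
        body = "\n".join(" ".join(format(v, ".6f") for v in row) for row in filled)
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    header = (
        f"ncols {obj.values.shape[1]}\n"
        f"nrows {obj.values.shape[0]}\n"
        f"xllcorner {obj.origin[0]:g}\n"
        f"yllcorner {obj.origin[1]:g}\n"
        f"cellsize {obj.cell_size:g}\n"
        f"NODATA_value {nodata:g}\n"
    )
    path.write_text(header + body + "\n")
    return path
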