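"""Distance-decay foraging kernels and the shared smoothing engine.

The probability of a pollinator visiting a cell at centre-to-centre distance
``d`` from its focal cell decays exponentially, ``w(d) = exp(-d / delta)``,
truncated at the foraging radius ``r`` and normalized so that the stencil
weights sum to one.  The same kernel-weighted averaging drives both the
exposure stage (hazard collected while foraging) and the service stage
(health delivered to crops), so it lives here as one engine with two
boundary treatments:

``renormalize``
    weights are rescaled to sum to one over the in-bounds part of the
    stencil, so edge cells average over their available neighbourhood;
``torus``
    periodic wrapping; useful for edge-free analytic checks.

Convolutions run through FFTs; correctness against a direct-sum double loop
is enforced in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

__all__ = ["KernelSpec", "build_kernel", "kernel_average"]

_EPS = 1e-300  # guards 0/0 where the whole stencil is out of bounds (cannot happen on non-empty grids)


@dataclass(frozen=True)
class KernelSpec:
    """Foraging kernel parameters.

    ``foraging_radius`` truncates the kernel; ``decay_length`` is the
    e-folding distance of the exponential decay (default half the radius).
    ``include_focal_cell`` keeps the d = 0 weight, reflecting that a forager
    also uses its own cell.
    """

    foraging_radius: float
    decay_length: float
    cell_size: float
    boundary_mode: str = "renormalize"
    include_focal_cell: bool = True

    def __post_init__(self) -> None:
        if self.foraging_radius <= 0 or self.decay_length <= 0:
            raise ValueError("foraging_radius and decay_length must be positive")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.foraging_radius < self.cell_size:
            raise ValueError("foraging_radius must be at least one cell size")
        if self.boundary_mode not in ("renormalize", "torus"):
            raise ValueError(f"unknown boundary_mode {self.boundary_mode!r}")

    @classmethod
    def for_radius(cls, foraging_radius: float, cell_size: float, **kw) -> "KernelSpec":
        """Spec with the default decay length of half the foraging radius."""
        return cls(foraging_radius, foraging_radius / 2.0, cell_size, **kw)


def build_kernel(spec: KernelSpec) -> np.ndarray:
    """Normalized square weight stencil of side ``2 floor(r/h) + 1``.

    Weight at centre-to-centre distance ``d``: ``exp(-d/delta)`` if
    ``d <= r`` else 0; the returned array sums to exactly 1.
    """
    radius_cells = int(np.floor(spec.foraging_radius / spec.cell_size))
    offsets = np.arange(-radius_cells, radius_cells + 1)
    dy, dx = np.meshgrid(offsets, offsets, indexing="ij")
    d = np.hypot(dy, dx) * spec.cell_size
    w = np.where(d <= spec.foraging_radius, np.exp(-d / spec.decay_length), 0.0)
    if not spec.include_focal_cell:
        w[radius_cells, radius_cells] = 0.0
    total = w.sum()
    if total <= 0:
        raise ValueError("kernel has no positive weight")
    return w / total


def _convolve_torus(field: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    kr, kc = kernel.shape
    nr, nc = field.shape
    if kr > nr or kc > nc:
        raise ValueError(
            f"torus mode requires the kernel ({kr}x{kc}) to fit inside the grid ({nr}x{nc})"
        )
    kpad = np.zeros_like(field, dtype=float)
    kpad[:kr, :kc] = kernel
    # centre the stencil on the origin of the periodic domain
    kpad = np.roll(kpad, shift=(-(kr // 2), -(kc // 2)), axis=(0, 1))
    out = np.fft.irfft2(np.fft.rfft2(field) * np.fft.rfft2(kpad), s=field.shape)
    return out


def kernel_average(
    field: np.ndarray,
    kernel: np.ndarray,
    boundary_mode: str = "renormalize",
) -> np.ndarray:
    """Kernel-weighted average of ``field`` at every cell.

    In ``renormalize`` mode the weighted sum is divided by the in-bounds
    weight mass, so a constant field maps to itself everywhere including
    edges; in ``torus`` mode the convolution wraps periodically.
    """
    field = np.asarray(field, dtype=float)
    if field.ndim != 2:
        raise ValueError("field must be 2-D")
    if kernel.ndim != 2 or kernel.shape[0] % 2 == 0 or kernel.shape[1] % 2 == 0:
        raise ValueError("kernel must be 2-D with odd side lengths")
    if boundary_mode == "torus":
        return _convolve_torus(field, kernel)
    if boundary_mode == "renormalize":
        num = fftconvolve(field, kernel, mode="same")
        den = _inbounds_weight(field.shape, kernel)
        return num / den
    raise ValueError(f"unknown boundary_mode {boundary_mode!r}")


_DEN_CACHE: dict[tuple, np.ndarray] = {}


def _inbounds_weight(shape: tuple[int, int], kernel: np.ndarray) -> np.ndarray:
    """In-bounds weight mass per cell (cached: reused for every hazard level)."""
    key = (shape, kernel.shape, hash(kernel.tobytes()))
    den = _DEN_CACHE.get(key)
    if den is None:
        den = fftconvolve(np.ones(shape), kernel, mode="same")
        np.maximum(den, _EPS, out=den)
        if len(_DEN_CACHE) > 32:
            _DEN_CACHE.clear()
        _DEN_CACHE[key] = den
    return den
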