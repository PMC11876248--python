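"""Neutral-landscape generation along composition and clustering gradients.

Binary habitat/agriculture rasters are produced by a three-step generator:
uniform white noise on a coarse grid, nearest-neighbour resampling to the
target cell size, and optional Gaussian smoothing.  Thresholding the
continuous field at the empirical quantile fixes the habitat share exactly,
so composition and configuration can be varied independently.  Spatial
clustering is quantified by the log-transformed landscape shape index
(log-LSI): low values mean compact, clustered land uses, high values mean
finely interspersed ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .grid import AGRICULTURE, BINARY_CODES, HABITAT, FieldMap, LandscapeGrid

__all__ = [
    "GeneratorSettings",
    "ClusteringGradient",
    "LandscapeReplicate",
    "ConfigurationError",
    "generate_random_field",
    "threshold_to_composition",
    "generate_landscape",
    "landscape_shape_index",
    "log_lsi",
    "build_clustering_gradient",
    "select_equally_spaced",
    "replicate_landscapes",
    "default_candidates",
]


class ConfigurationError(ValueError):
    """Raised when generator or gradient settings are inconsistent."""


@dataclass(frozen=True)
class GeneratorSettings:
    """One neutral-landscape parameterization.

    ``coarse_cell_size`` controls blockiness (noise is drawn on this grid and
    resampled down), ``autocorrelation_length`` is the standard deviation, in
    metres, of the Gaussian smoother applied after resampling (0 disables
    smoothing).  Larger values of either knob give more clustered patterns.
    """

    habitat_fraction: float
    coarse_cell_size: float
    autocorrelation_length: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.habitat_fraction <= 1.0:
            raise ConfigurationError("habitat_fraction must be in [0, 1]")
        if self.coarse_cell_size <= 0:
            raise ConfigurationError("coarse_cell_size must be positive")
        if self.autocorrelation_length < 0:
            raise ConfigurationError("autocorrelation_length must be >= 0")


@dataclass(frozen=True)
class ClusteringGradient:
    """Ordered clustering levels for one habitat fraction.

    Levels run from clustered (low log-LSI) to dispersed (high log-LSI);
    ``level_log_lsi`` holds the estimated mean log-LSI of each level.
    """

    habitat_fraction: float
    levels: tuple[GeneratorSettings, ...]
    level_log_lsi: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.level_log_lsi):
            raise ConfigurationError("levels and level_log_lsi must align")
        diffs = np.diff(self.level_log_lsi)
        if len(diffs) and not np.all(diffs > 0):
            raise ConfigurationError("level_log_lsi must be strictly increasing")

    @property
    def most_clustered(self) -> GeneratorSettings:
        return self.levels[0]

    @property
    def most_dispersed(self) -> GeneratorSettings:
        return self.levels[-1]


@dataclass(frozen=True)
class LandscapeReplicate:
    """One generated landscape with its provenance within a gradient."""

    level: int
    replicate: int
    seed: int
    grid: LandscapeGrid


def generate_random_field(
    settings: GeneratorSettings,
    target_cell_size: float,
    extent: tuple[float, float],
) -> FieldMap:
    """Continuous random field at the target resolution.

    Uniform(0,1) noise is sampled on the coarse grid, resampled to the target
    cell size by nearest neighbour, and smoothed with a wrap-around Gaussian
    filter of standard deviation ``autocorrelation_length``.  Deterministic
    given ``settings.seed``.
    """
    width, height = float(extent[0]), float(extent[1])
    if width <= 0 or height <= 0:
        raise ConfigurationError("extent must be positive")
    coarse = settings.coarse_cell_size
    factor = coarse / target_cell_size
    if abs(factor - round(factor)) > 1e-9 or round(factor) < 1:
        raise ConfigurationError(
            f"coarse_cell_size {coarse} is not an integer multiple of "
            f"target cell size {target_cell_size}"
        )
    factor = int(round(factor))
    for dim, name in ((width, "width"), (height, "height")):
        if abs(dim / coarse - round(dim / coarse)) > 1e-9:
            raise ConfigurationError(f"extent {name} {dim} not divisible by coarse cell size {coarse}")
    ncoarse_rows = int(round(height / coarse))
    ncoarse_cols = int(round(width / coarse))
    rng = np.random.default_rng(settings.seed)
    noise = rng.random((ncoarse_rows, ncoarse_cols))
    fine = np.repeat(np.repeat(noise, factor, axis=0), factor, axis=1)
    if settings.autocorrelation_length > 0:
        sigma_cells = settings.autocorrelation_length / target_cell_size
        fine = ndimage.gaussian_filter(fine, sigma=sigma_cells, mode="wrap")
    return FieldMap(fine, quantity="random", cell_size=target_cell_size)


def threshold_to_composition(field: FieldMap, p: float) -> LandscapeGrid:
    """Binary landscape with exactly ``round(p * N)`` habitat cells.

    Cells are ranked by field value; the top share becomes HABITAT.  Ties are
    broken deterministically by flat cell index (stable sort), so constant
    blocks from coarse resampling still yield the exact habitat count.
    """
    if not 0.0 <= p <= 1.0:
        raise ConfigurationError("habitat fraction must be in [0, 1]")
    flat = field.values.ravel()
    n_habitat = int(round(p * flat.size))
    values = np.full(flat.size, AGRICULTURE, dtype=np.int32)
    if n_habitat > 0:
        order = np.argsort(-flat, kind="stable")
        values[order[:n_habitat]] = HABITAT
    return LandscapeGrid(
        values.reshape(field.values.shape),
        cell_size=field.cell_size,
        origin=field.origin,
        class_codes=dict(BINARY_CODES),
    )


def generate_landscape(
    settings: GeneratorSettings,
    target_cell_size: float,
    extent: tuple[float, float],
) -> LandscapeGrid:
    """Convenience: random field + composition threshold in one call."""
    field = generate_random_field(settings, target_cell_size, extent)
    return threshold_to_composition(field, settings.habitat_fraction)


def landscape_shape_index(grid: LandscapeGrid) -> float:
    """Landscape shape index LSI = 0.25 E* / sqrt(A).

    ``E*`` is the total edge length: the full outer landscape boundary plus
    every 4-neighbour cell boundary whose two cells hold different classes;
    ``A`` is the landscape area.  LSI is 1 for a single-class square
    landscape and grows with interspersion.
    """
    v = grid.values
    h = grid.cell_size
    outer = 2.0 * (grid.nrows + grid.ncols) * h
    internal = (
        int(np.count_nonzero(v[:, 1:] != v[:, :-1]))
        + int(np.count_nonzero(v[1:, :] != v[:-1, :]))
    ) * h
    return 0.25 * (outer + internal) / math.sqrt(grid.area)


def log_lsi(grid: LandscapeGrid) -> float:
    """Natural log of the landscape shape index; >= 0, 0 iff single-class square."""
    return math.log(landscape_shape_index(grid))


def default_candidates(habitat_fraction: float, cell_size: float = 10.0) -> list[GeneratorSettings]:
    """Default generator candidates spanning dispersed to clustered patterns.

    The list runs from plain white noise at the target resolution (most
    dispersed) to coarse blocks with strong smoothing (most clustered); the
    gradient builder measures and orders them by realized log-LSI.
    """
    knobs = [
        (1, 0.0),
        (2, 0.0),
        (2, 1.0),
        (4, 2.0),
        (8, 4.0),
        (10, 6.0),
        (20, 12.0),
        (20, 25.0),
    ]
    return [
        GeneratorSettings(
            habitat_fraction=habitat_fraction,
            coarse_cell_size=k * cell_size,
            autocorrelation_length=a * cell_size,
        )
        for k, a in knobs
    ]


def _estimate_mean_log_lsi(
    settings: GeneratorSettings,
    target_cell_size: float,
    extent: tuple[float, float],
    n_reps: int,
    base_seed: int,
) -> float:
    ss = np.random.SeedSequence([base_seed, 0x6C5]).generate_state(n_reps)
    vals = []
    for s in ss:
        grid = generate_landscape(replace(settings, seed=int(s)), target_cell_size, extent)
        vals.append(log_lsi(grid))
    return float(np.mean(vals))


def select_equally_spaced(means: Sequence[float], n_levels: int) -> list[int]:
    """Indices of the ``n_levels`` values minimizing total absolute deviation
    from an equally spaced sequence between min and max.

    Solved by monotone-assignment dynamic programming: with both the values
    and the target sequence sorted, an optimal assignment never crosses, so
    a left-to-right scan suffices.  Returns indices into ``means`` ordered
    by increasing value.
    """
    means = np.asarray(means, dtype=float)
    m = means.size
    if n_levels < 1 or n_levels > m:
        raise ConfigurationError(f"n_levels must be in [1, {m}]")
    order = np.argsort(means, kind="stable")
    sorted_means = means[order]
    targets = np.linspace(sorted_means[0], sorted_means[-1], n_levels)

    dp = np.full((m + 1, n_levels + 1), np.inf)
    dp[:, 0] = 0.0
    take = np.zeros((m + 1, n_levels + 1), dtype=bool)
    for i in range(1, m + 1):
        for j in range(1, min(i, n_levels) + 1):
            skip = dp[i - 1, j]
            cost = dp[i - 1, j - 1] + abs(sorted_means[i - 1] - targets[j - 1])
            if cost <= skip:
                dp[i, j] = cost
                take[i, j] = True
            else:
                dp[i, j] = skip
    picked: list[int] = []
    i, j = m, n_levels
    while j > 0:
        if take[i, j]:
            picked.append(i - 1)
            j -= 1
        i -= 1
    picked.reverse()
    return [int(order[k]) for k in picked]


def build_clustering_gradient(
    p: float,
    candidates: Sequence[GeneratorSettings],
    n_levels: int,
    reps_for_estimation: int = 10,
    target_cell_size: float = 10.0,
    extent: tuple[float, float] = (2000.0, 2000.0),
    base_seed: int = 0,
) -> ClusteringGradient:
    """Select ``n_levels`` candidates at approximately equal log-LSI spacing.

    Each candidate's mean log-LSI is estimated over ``reps_for_estimation``
    seeds; the subset minimizing the total absolute deviation from an equally
    spaced sequence between the candidate minimum and maximum is found by
    monotone-assignment dynamic programming (optimal since both the candidate
    means and the target sequence are sorted).
    """
    if n_levels < 1:
        raise ConfigurationError("n_levels must be >= 1")
    cands = [replace(c, habitat_fraction=p) for c in candidates]
    distinct = {(c.coarse_cell_size, c.autocorrelation_length) for c in cands}
    if len(distinct) < len(cands):
        raise ConfigurationError("duplicate candidate settings")
    if len(cands) < n_levels:
        raise ConfigurationError(f"need at least {n_levels} candidates, got {len(cands)}")
    means = np.array(
        [
            _estimate_mean_log_lsi(c, target_cell_size, extent, reps_for_estimation, base_seed)
            for c in cands
        ]
    )
    if np.ptp(means) < 1e-12 and n_levels > 1:
        raise ConfigurationError("degenerate gradient: all candidates have identical log-LSI")
    sel = select_equally_spaced(means, n_levels)
    level_means = [float(means[k]) for k in sel]
    if len(level_means) > 1 and np.any(np.diff(level_means) <= 0):
        raise ConfigurationError("selected levels do not have strictly increasing log-LSI")
    return ClusteringGradient(
        habitat_fraction=p,
        levels=tuple(cands[k] for k in sel),
        level_log_lsi=tuple(level_means),
    )


def replicate_landscapes(
    gradient: ClusteringGradient,
    n_reps: int,
    base_seed: int,
    target_cell_size: float = 10.0,
    extent: tuple[float, float] = (2000.0, 2000.0),
) -> list[LandscapeReplicate]:
    """``n_reps`` seeded landscapes per gradient level.

    Seeds derive from ``base_seed`` through a splittable NumPy SeedSequence
    keyed by (level, replicate), so runs are reproducible and collision-free.
    """
    if n_reps < 1:
        raise ConfigurationError("n_reps must be >= 1")
    out: list[LandscapeReplicate] = []
    for li, settings in enumerate(gradient.levels):
        for ri in range(n_reps):
            seed = int(np.random.SeedSequence([base_seed, li, ri]).generate_state(1)[0])
            grid = generate_landscape(
                replace(settings, seed=seed), target_cell_size, extent
            )
            out.append(LandscapeReplicate(level=li, replicate=ri, seed=seed, grid=grid))
    return out
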