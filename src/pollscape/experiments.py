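"""Factorial gradient experiment: habitat % x clustering x hazard x replicate.

For every habitat-percentage step a clustering gradient is built once, the
replicate landscapes are generated once per (level, replicate), and each
landscape is re-used across all hazard levels (paired design), so service
differences across hazard within a replicate are attributable to hazard
alone.  Landscape-level summaries are the unweighted means of service over
demand cells and of health over habitat cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd

from .grid import LandscapeGrid
from .kernels import KernelSpec
from .model import ClassTable, ModelResult, run_model
from .synthesis import (
    ClusteringGradient,
    ConfigurationError,
    GeneratorSettings,
    build_clustering_gradient,
    default_candidates,
    log_lsi,
    replicate_landscapes,
)

__all__ = [
    "ExperimentDesign",
    "summarize_landscape",
    "run_gradient_experiment",
    "aggregate_results",
    "paired_setting_comparison",
]

#: habitat-percentage steps, denser at the low end where potential pollinator
#: habitat (hedgerows, tree lines) typically sits in EU agricultural land
DEFAULT_HABITAT_PERCENTAGES = (3.0, 5.0, 10.0, 15.0, 30.0, 50.0)
#: mortality-hazard gradient aligned with pesticide side-effect classes
DEFAULT_HAZARD_LEVELS = (0.0, 25.0, 50.0, 75.0, 100.0)


@dataclass(frozen=True)
class ExperimentDesign:
    """Full factorial design with the study's default gradients."""

    habitat_percentages: tuple[float, ...] = DEFAULT_HABITAT_PERCENTAGES
    hazard_levels: tuple[float, ...] = DEFAULT_HAZARD_LEVELS
    n_levels: int = 5
    n_reps: int = 50
    base_seed: int = 0
    extent: tuple[float, float] = (2000.0, 2000.0)
    cell_size: float = 10.0
    foraging_radius: float = 500.0
    decay_length: float | None = None  # None -> radius / 2
    boundary_mode: str = "renormalize"
    candidates: tuple[GeneratorSettings, ...] | None = None
    reps_for_estimation: int = 10

    def kernel_spec(self) -> KernelSpec:
        delta = self.decay_length if self.decay_length is not None else self.foraging_radius / 2.0
        return KernelSpec(
            self.foraging_radius, delta, self.cell_size, boundary_mode=self.boundary_mode
        )

    def candidate_list(self, p: float) -> list[GeneratorSettings]:
        if self.candidates is not None:
            return list(self.candidates)
        return default_candidates(p, self.cell_size)


def summarize_landscape(
    result: ModelResult, grid: LandscapeGrid, classes: ClassTable
) -> tuple[float, float, float]:
    """(mean service over demand cells, mean health over habitat cells, log-LSI).

    An empty demand or habitat set yields NaN for the corresponding mean —
    the summary is flagged undefined rather than silently zero.
    """
    return result.service.mean(), result.health.mean(), log_lsi(grid)


def run_gradient_experiment(design: ExperimentDesign) -> pd.DataFrame:
    """One record per (habitat %, clustering level, hazard, replicate).

    Landscapes are shared across hazard levels within a replicate; the whole
    table is reproducible from ``design.base_seed``.
    """
    spec = design.kernel_spec()
    records: list[dict] = []
    for fi, pct in enumerate(design.habitat_percentages):
        p = pct / 100.0
        gradient = build_clustering_gradient(
            p,
            design.candidate_list(p),
            design.n_levels,
            reps_for_estimation=design.reps_for_estimation,
            target_cell_size=design.cell_size,
            extent=design.extent,
            base_seed=_mix(design.base_seed, fi),
        )
        reps = replicate_landscapes(
            gradient,
            design.n_reps,
            base_seed=_mix(design.base_seed, fi, 1),
            target_cell_size=design.cell_size,
            extent=design.extent,
        )
        for rep in reps:
            realized_log_lsi = log_lsi(rep.grid)
            for hazard in design.hazard_levels:
                result = run_model(rep.grid, ClassTable.binary(hazard), spec)
                mean_service, mean_health, _ = summarize_landscape(
                    result, rep.grid, ClassTable.binary(hazard)
                )
                records.append(
                    {
                        "habitat_pct": pct,
                        "clustering_level": rep.level,
                        "log_lsi": realized_log_lsi,
                        "hazard": hazard,
                        "replicate": rep.replicate,
                        "seed": rep.seed,
                        "mean_service": mean_service,
                        "mean_health": mean_health,
                    }
                )
    return pd.DataFrame.from_records(records)


def aggregate_results(table: pd.DataFrame) -> pd.DataFrame:
    """Mean/sd of the landscape summaries per design cell (as plotted)."""
    grouped = table.groupby(["habitat_pct", "clustering_level", "hazard"], sort=True)
    agg = grouped.agg(
        mean_service=("mean_service", "mean"),
        sd_service=("mean_service", "std"),
        mean_health=("mean_health", "mean"),
        sd_health=("mean_health", "std"),
        mean_log_lsi=("log_lsi", "mean"),
        n=("mean_service", "size"),
    ).reset_index()
    return agg


def paired_setting_comparison(
    habitat_pct: float,
    settings_a: GeneratorSettings,
    settings_b: GeneratorSettings,
    hazard_levels: Sequence[float],
    n_reps: int,
    base_seed: int,
    extent: tuple[float, float] = (2000.0, 2000.0),
    cell_size: float = 10.0,
    spec: KernelSpec | None = None,
) -> pd.DataFrame:
    """Paired replicate comparison of two generator settings.

    Both settings are run on replicate seeds derived from the same base seed
    and each landscape is evaluated at every hazard level.  Columns:
    setting ('a'/'b'), hazard, replicate, mean_service, mean_health, log_lsi.
    """
    if n_reps < 1:
        raise ConfigurationError("n_reps must be >= 1")
    if spec is None:
        spec = KernelSpec.for_radius(500.0, cell_size)
    p = habitat_pct / 100.0
    gradients = {
        "a": ClusteringGradient(p, (settings_a,), (0.0,)),
        "b": ClusteringGradient(p, (settings_b,), (0.0,)),
    }
    records: list[dict] = []
    for label, grad in gradients.items():
        reps = replicate_landscapes(
            grad, n_reps, base_seed=base_seed, target_cell_size=cell_size, extent=extent
        )
        for rep in reps:
            ll = log_lsi(rep.grid)
            for hazard in hazard_levels:
                result = run_model(rep.grid, ClassTable.binary(hazard), spec)
                records.append(
                    {
                        "setting": label,
                        "hazard": hazard,
                        "replicate": rep.replicate,
                        "mean_service": result.service.mean(),
                        "mean_health": result.health.mean(),
                        "log_lsi": ll,
                    }
                )
    return pd.DataFrame.from_records(records)


def _mix(base_seed: int, *keys: int) -> int:
    """Derived 31-bit seed from a splittable sequence (no collisions)."""
    return int(np.random.SeedSequence([base_seed, *keys]).generate_state(1)[0] % (2**31))
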