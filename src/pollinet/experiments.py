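"""Deforestation-gradient experiments and sensitivity analysis.

The default design mirrors the in-silico study the package exists to
re-run: 11 forest-cover levels (0%, 10%, ..., 100%) x 10 replicate
fractal landscapes (Hurst exponent 0.9) = 110 simulated maps.  Each
replicate generates one base surface; all cover levels of that replicate
threshold the *same* surface, so habitat loss is sequential over one
landscape.  Every run records the six landscape metrics and the five
network metrics in a tidy table, one row per (level, replicate).

Seeds derive from a single ``base_seed`` via numpy SeedSequence:
``[base_seed, replicate]`` for the surface and
``[base_seed, replicate, level_index]`` for the simulation, so surfaces
are shared across levels and runs may execute in any order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import landmetrics, netmetrics
from .landscapes import generate_surface, make_gradient
from .simulator import (
    CommunityConfig,
    MovementConfig,
    allocate_diets,
    default_community,
    run_simulation,
)

__all__ = [
    "ExperimentDesign",
    "run_experiment",
    "summarize_by_level",
    "run_sensitivity",
    "RESULT_COLUMNS",
]

logger = logging.getLogger(__name__)

DEFAULT_LEVELS = tuple(np.round(np.arange(0, 11) / 10, 1))

RESULT_COLUMNS = (
    "level", "replicate", "surface_seed", "sim_seed",
    "pland", "area_mn", "area_am", "shape_mn", "shape_am", "connect",
    "connectance", "connectance_full", "nestedness", "h2", "size", "asymmetry",
    "total_visits", "n_ticks",
)


def _seed_int(*keys: int) -> int:
    """A reproducible 31-bit seed from a key tuple."""
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] >> 1)


@dataclass(frozen=True)
class ExperimentDesign:
    cover_levels: tuple[float, ...] = DEFAULT_LEVELS
    n_replicates: int = 10
    hurst: float = 0.9
    base_seed: int = 5
    community: CommunityConfig | None = None  # None -> default, diets from base_seed
    movement: MovementConfig = field(default_factory=MovementConfig)
    connectivity: int = 8
    connect_threshold: float = 50.0
    n_rows: int = 100
    n_cols: int = 100
    sensitivity_reallocations: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")
        if not self.cover_levels:
            raise ValueError("cover_levels must be non-empty")

    @property
    def n_runs(self) -> int:
        return len(self.cover_levels) * self.n_replicates

    def resolved_community(self) -> CommunityConfig:
        if self.community is not None:
            return self.community
        return default_community(seed=_seed_int(self.base_seed, 0xD1E7))


def run_experiment(design: ExperimentDesign, progress: bool = False) -> pd.DataFrame:
    """Run the full design and return one tidy row per (level, replicate).

    The ``connectance`` column uses the pruned active-matrix convention
    (the one the original field analyses used); ``connectance_full``
    keeps the fixed 20 x 20 denominator.  Nestedness (NODF) and H2' are
    NaN for degenerate networks and left as missing values.
    """
    community = design.resolved_community()
    rows = []
    for rep in range(design.n_replicates):
        surface_seed = _seed_int(design.base_seed, rep)
        surface = generate_surface(
            design.hurst, surface_seed, design.n_rows, design.n_cols
        )
        gradient = make_gradient(surface, design.cover_levels)
        for li, (level, grid) in enumerate(zip(gradient.levels, gradient.grids)):
            sim_seed = _seed_int(design.base_seed, rep, li)
            try:
                lm = landmetrics.compute_metrics(
                    grid,
                    connectivity=design.connectivity,
                    threshold=design.connect_threshold,
                )
                result = run_simulation(
                    grid, community, design.movement, seed=sim_seed
                )
                nm = netmetrics.compute_metrics(result.visits)
            except Exception as exc:
                raise RuntimeError(
                    f"run failed at level={level} replicate={rep} seed={sim_seed}"
                ) from exc
            rows.append(
                {
                    "level": level,
                    "replicate": rep,
                    "surface_seed": surface_seed,
                    "sim_seed": sim_seed,
                    **lm.as_dict(),
                    "connectance": nm.connectance_active,
                    "connectance_full": nm.connectance,
                    "nestedness": nm.nestedness,
                    "h2": nm.h2,
                    "size": nm.size,
                    "asymmetry": nm.asymmetry,
                    "total_visits": int(result.visits.counts.sum()),
                    "n_ticks": result.n_ticks,
                }
            )
            if progress:
                logger.info("level %.2f replicate %d done", level, rep)
    table = pd.DataFrame(rows, columns=list(RESULT_COLUMNS))
    return table.sort_values(["level", "replicate"], ignore_index=True)


def summarize_by_level(table: pd.DataFrame) -> pd.DataFrame:
    """Per-level mean and standard error of the mean for every metric."""
    metrics = [
        c
        for c in table.columns
        if c not in ("level", "replicate", "surface_seed", "sim_seed")
    ]
    grouped = table.groupby("level")[metrics]
    mean = grouped.mean()
    se = grouped.sem(ddof=1)
    out = pd.concat({"mean": mean, "se": se}, axis=1)
    out.columns = [f"{metric}_{stat}" for stat, metric in out.columns]
    return out.reset_index()


def run_sensitivity(
    design: ExperimentDesign, progress: bool = False
) -> pd.DataFrame:
    """Re-run the design under freshly seeded bee-to-flower allocations.

    Returns the concatenation of one full results table per allocation
    (column ``allocation``: 0 is the design's own community, k >= 1 are
    reallocations).  Landscapes and simulation seeds are shared across
    allocations, so landscape metrics are identical between tables and
    only the network side varies.  An empty frame is returned when
    ``sensitivity_reallocations`` is 0.
    """
    n = design.sensitivity_reallocations
    if n < 1:
        return pd.DataFrame(columns=["allocation", *RESULT_COLUMNS])
    base = design.resolved_community()
    tables = []
    for k in range(n + 1):
        if k == 0:
            community = base
        else:
            rng = np.random.default_rng(_seed_int(design.base_seed, 0xA110C, k))
            community = CommunityConfig(
                bees=allocate_diets(base.bees, base.flowers, rng),
                flowers=base.flowers,
            )
        sub = ExperimentDesign(
            cover_levels=design.cover_levels,
            n_replicates=design.n_replicates,
            hurst=design.hurst,
            base_seed=design.base_seed,
            community=community,
            movement=design.movement,
            connectivity=design.connectivity,
            connect_threshold=design.connect_threshold,
            n_rows=design.n_rows,
            n_cols=design.n_cols,
        )
        table = run_experiment(sub, progress=progress)
        table.insert(0, "allocation", k)
        tables.append(table)
    return pd.concat(tables, ignore_index=True)
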