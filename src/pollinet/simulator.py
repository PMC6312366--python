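"""Agent-based model of bee foraging flights and flower visitation.

A community of bee species forages over a binary forest/open landscape.
Each species belongs to one of three functional groups that differ in
diet breadth, flight energy and nesting constraint:

==================  =====  ======  ==============  ============
group               diet   energy  nesting         species (default)
==================  =====  ======  ==============  ============
specialist          1      50      forest only     9
generalist          4      100     anywhere        8
super-generalist    8      200     anywhere        3
==================  =====  ======  ==============  ============

Energy is measured in cell-lengths of flight (1 unit = 10 m).  Flower
species (default 20; half restricted to forest, half to open vegetation)
each occupy a fixed number of randomly chosen grid cells of their guild.

Movement is a correlated random walk: at each tick a bee turns by an
angle drawn from a wrapped-normal distribution and advances by a step
drawn from a truncated normal (mean 2 cells = 20 m).  The world does not
wrap; bees reflect off the boundary.  A visit is recorded whenever a
bee's post-move cell hosts a flower species in its diet.  A bee's flight
ends when its energy is exhausted; return flights to the nest are not
modelled.  The run stops when all bees are dead or ``max_ticks`` (150)
is reached, and returns the bee-species x flower-species visit matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .landscapes import FOREST, OPEN, LandscapeGrid

__all__ = [
    "SPECIALIST",
    "GENERALIST",
    "SUPER_GENERALIST",
    "GROUP_DEFAULTS",
    "BeeSpeciesProfile",
    "FlowerSpeciesProfile",
    "CommunityConfig",
    "MovementConfig",
    "FlowerPlacement",
    "VisitMatrix",
    "SimulationResult",
    "ConfigError",
    "allocate_diets",
    "default_community",
    "place_flowers",
    "place_nests",
    "run_simulation",
]

logger = logging.getLogger(__name__)

SPECIALIST = "specialist"
GENERALIST = "generalist"
SUPER_GENERALIST = "super_generalist"

#: per-group (diet size, initial energy in cell-lengths, default species count)
GROUP_DEFAULTS = {
    SPECIALIST: {"diet_size": 1, "energy": 50.0, "n_species": 9},
    GENERALIST: {"diet_size": 4, "energy": 100.0, "n_species": 8},
    SUPER_GENERALIST: {"diet_size": 8, "energy": 200.0, "n_species": 3},
}


class ConfigError(ValueError):
    """Inconsistent community or movement configuration."""


@dataclass(frozen=True)
class BeeSpeciesProfile:
    species_id: int
    group: str
    initial_energy: float
    diet: tuple[int, ...]
    nest_habitat: str  # "forest_only" or "any"
    n_individuals: int = 10

    def __post_init__(self) -> None:
        if self.group not in GROUP_DEFAULTS:
            raise ConfigError(f"unknown group {self.group!r}")
        if self.initial_energy <= 0:
            raise ConfigError("initial_energy must be positive")
        if self.nest_habitat not in ("forest_only", "any"):
            raise ConfigError(f"unknown nest_habitat {self.nest_habitat!r}")
        if len(set(self.diet)) != len(self.diet):
            raise ConfigError("diet must not repeat flower species")


@dataclass(frozen=True)
class FlowerSpeciesProfile:
    flower_id: int
    guild: str  # "forest" or "open"
    n_cells: int = 20

    def __post_init__(self) -> None:
        if self.guild not in ("forest", "open"):
            raise ConfigError(f"unknown guild {self.guild!r}")
        if self.n_cells < 0:
            raise ConfigError("n_cells must be non-negative")


@dataclass(frozen=True)
class CommunityConfig:
    bees: tuple[BeeSpeciesProfile, ...]
    flowers: tuple[FlowerSpeciesProfile, ...]

    def __post_init__(self) -> None:
        flower_ids = {f.flower_id for f in self.flowers}
        if len(flower_ids) != len(self.flowers):
            raise ConfigError("duplicate flower ids")
        bee_ids = [b.species_id for b in self.bees]
        if len(set(bee_ids)) != len(bee_ids):
            raise ConfigError("duplicate bee species ids")
        for bee in self.bees:
            unknown = set(bee.diet) - flower_ids
            if unknown:
                raise ConfigError(
                    f"bee {bee.species_id} diet references unknown flowers {sorted(unknown)}"
                )

    @property
    def bee_ids(self) -> tuple[int, ...]:
        return tuple(b.species_id for b in self.bees)

    @property
    def flower_ids(self) -> tuple[int, ...]:
        return tuple(f.flower_id for f in self.flowers)


@dataclass(frozen=True)
class MovementConfig:
    """Correlated-random-walk parameters (lengths in cell units)."""

    step_mean: float = 2.0
    step_sd: float = 0.5
    step_min: float = 0.1
    turn_sd_deg: float = 40.0
    max_ticks: int = 150
    boundary: str = "reflect"

    def __post_init__(self) -> None:
        if self.step_min <= 0:
            raise ConfigError("step_min must be positive")
        if self.max_ticks < 1:
            raise ConfigError("max_ticks must be at least 1")
        if self.boundary != "reflect":
            raise ConfigError("only reflecting boundaries are supported")


def allocate_diets(
    bees: Sequence[BeeSpeciesProfile],
    flowers: Sequence[FlowerSpeciesProfile],
    rng: np.random.Generator,
) -> tuple[BeeSpeciesProfile, ...]:
    """Randomly allocate each bee species its diet of flower species.

    Diet sizes follow each bee's functional group (1 / 4 / 8); flower
    species are drawn without replacement within each bee's draw, so the
    same flower may feed several bee species.  Re-running with a new rng
    supports the sensitivity analysis over diet reallocations.
    """
    flower_ids = np.array([f.flower_id for f in flowers])
    out = []
    for bee in bees:
        k = GROUP_DEFAULTS[bee.group]["diet_size"]
        if k > flower_ids.size:
            raise ConfigError(
                f"diet size {k} exceeds the {flower_ids.size} flower species"
            )
        diet = tuple(sorted(int(f) for f in rng.choice(flower_ids, size=k, replace=False)))
        out.append(replace(bee, diet=diet))
    return tuple(out)


def default_community(
    seed: int | np.random.Generator = 0,
    n_individuals: int = 10,
    flower_cells: int = 20,
) -> CommunityConfig:
    """The default 20-bee / 20-flower community with randomly drawn diets.

    Bees 1-9 are specialists, 10-17 generalists, 18-20 super-generalists;
    flowers 1-10 are restricted to forest and 11-20 to open vegetation.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flowers = tuple(
        FlowerSpeciesProfile(
            flower_id=i, guild="forest" if i <= 10 else "open", n_cells=flower_cells
        )
        for i in range(1, 21)
    )
    bees = []
    sid = 1
    for group in (SPECIALIST, GENERALIST, SUPER_GENERALIST):
        spec = GROUP_DEFAULTS[group]
        for _ in range(spec["n_species"]):
            bees.append(
                BeeSpeciesProfile(
                    species_id=sid,
                    group=group,
                    initial_energy=spec["energy"],
                    diet=(),
                    nest_habitat="forest_only" if group == SPECIALIST else "any",
                    n_individuals=n_individuals,
                )
            )
            sid += 1
    bees = allocate_diets(bees, flowers, rng)
    return CommunityConfig(bees=bees, flowers=flowers)


# ---------------------------------------------------------------------------
# placement


@dataclass(frozen=True)
class FlowerPlacement:
    """Map from grid cell to the (single) flower species occupying it."""

    flower_of_cell: np.ndarray  # int array, grid-shaped; 0 = no flower
    cells_of: dict[int, np.ndarray]  # flower_id -> flat cell indices

    def n_placed(self, flower_id: int) -> int:
        return self.cells_of.get(flower_id, np.empty(0)).size


def place_flowers(
    grid: LandscapeGrid,
    flowers: Sequence[FlowerSpeciesProfile],
    rng: np.random.Generator,
) -> FlowerPlacement:
    """Place each flower species on distinct random cells of its guild.

    Cells are unique across all species.  When a guild runs out of
    eligible cells (e.g. at 0% or 100% forest cover) a species receives
    as many cells as remain and a warning is logged.
    """
    cover = grid.cover.ravel()
    available = {
        "forest": list(np.flatnonzero(cover == FOREST)),
        "open": list(np.flatnonzero(cover == OPEN)),
    }
    for guild in available:
        rng.shuffle(available[guild])
    flower_of_cell = np.zeros(grid.n_cells, dtype=np.int32)
    cells_of: dict[int, np.ndarray] = {}
    for fl in flowers:
        pool = available[fl.guild]
        take = min(fl.n_cells, len(pool))
        if take < fl.n_cells:
            logger.warning(
                "flower %d (%s guild): only %d of %d cells available",
                fl.flower_id, fl.guild, take, fl.n_cells,
            )
        cells = np.array(sorted(pool[:take]), dtype=np.int64)
        del pool[:take]
        flower_of_cell[cells] = fl.flower_id
        cells_of[fl.flower_id] = cells
    return FlowerPlacement(
        flower_of_cell=flower_of_cell.reshape(grid.cover.shape), cells_of=cells_of
    )


def place_nests(
    grid: LandscapeGrid,
    bees: Sequence[BeeSpeciesProfile],
    rng: np.random.Generator,
) -> dict[int, tuple[int, int] | None]:
    """Draw one nest cell per bee species.

    Specialists nest uniformly on forest cells; other groups anywhere.
    A specialist species on a landscape without forest is marked absent
    (mapped to None) and sits out the run.
    """
    forest_cells = np.flatnonzero(grid.cover.ravel() == FOREST)
    all_cells = np.arange(grid.n_cells)
    nests: dict[int, tuple[int, int] | None] = {}
    for bee in bees:
        pool = forest_cells if bee.nest_habitat == "forest_only" else all_cells
        if pool.size == 0:
            logger.warning(
                "bee species %d cannot nest (no %s habitat); absent this run",
                bee.species_id, bee.nest_habitat,
            )
            nests[bee.species_id] = None
            continue
        flat = int(rng.choice(pool))
        nests[bee.species_id] = (flat // grid.n_cols, flat % grid.n_cols)
    return nests


# ---------------------------------------------------------------------------
# simulation


@dataclass(frozen=True)
class VisitMatrix:
    """Integer bee-species x flower-species matrix of recorded visits."""

    counts: np.ndarray
    bee_ids: tuple[int, ...]
    flower_ids: tuple[int, ...]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.counts, index=list(self.bee_ids), columns=list(self.flower_ids)
        )

    @classmethod
    def from_frame(cls, frame) -> "VisitMatrix":
        counts = frame.to_numpy(dtype=np.int64)
        return cls(
            counts=counts,
            bee_ids=tuple(int(i) for i in frame.index),
            flower_ids=tuple(int(c) for c in frame.columns),
        )


@dataclass(frozen=True)
class AgentSummary:
    """Per-agent diagnostics of one run."""

    species_id: np.ndarray
    initial_energy: np.ndarray
    path_length: np.ndarray
    death_tick: np.ndarray  # tick at which the agent died; -1 if alive at end


@dataclass(frozen=True)
class SimulationResult:
    visits: VisitMatrix
    agents: AgentSummary
    placement: FlowerPlacement
    nests: dict[int, tuple[int, int] | None]
    n_ticks: int
    trajectories: np.ndarray | None = None

    @property
    def all_dead_tick(self) -> int:
        """First tick by which every agent had exhausted its energy."""
        if (self.agents.death_tick < 0).any():
            return -1
        if self.agents.death_tick.size == 0:
            return 0
        return int(self.agents.death_tick.max())


def _reflect(pos: np.ndarray, vec: np.ndarray, upper: float) -> None:
    """Fold coordinates into [0, upper], mirroring the movement vector."""
    for _ in range(64):
        below = pos < 0
        above = pos > upper
        if not (below.any() or above.any()):
            return
        pos[below] = -pos[below]
        vec[below] = -vec[below]
        pos[above] = 2 * upper - pos[above]
        vec[above] = -vec[above]
    raise RuntimeError("boundary reflection failed to converge")


def run_simulation(
    grid: LandscapeGrid,
    community: CommunityConfig,
    movement: MovementConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
    collect_trajectories: bool = False,
) -> SimulationResult:
    """Run one foraging simulation and return the visit matrix.

    All individuals of a species start at its nest cell centre with
    independent uniform headings.  Each tick, every living bee turns,
    steps, pays energy equal to the distance flown, and records a visit
    if its new cell hosts a diet flower.  Bees that overdraw their
    energy still complete the drawn step, then die.  Fully reproducible
    from (configs, seed).
    """
    movement = movement or MovementConfig()
    for bee in community.bees:
        if not bee.diet:
            raise ConfigError(
                f"bee species {bee.species_id} has an empty diet; "
                "allocate diets before running"
            )
    rng = np.random.default_rng(seed)
    placement = place_flowers(grid, community.flowers, rng)
    nests = place_nests(grid, community.bees, rng)

    bee_index = {b: i for i, b in enumerate(community.bee_ids)}
    flower_index = {f: j for j, f in enumerate(community.flower_ids)}
    n_bees = len(community.bee_ids)
    n_flowers = len(community.flower_ids)

    # diet mask: diet_ok[species_row, flower_row]
    diet_ok = np.zeros((n_bees, n_flowers), dtype=bool)
    for bee in community.bees:
        for f in bee.diet:
            diet_ok[bee_index[bee.species_id], flower_index[f]] = True

    # flower row per cell; -1 = none
    flower_row_of_cell = np.full(grid.cover.shape, -1, dtype=np.int32)
    for f, cells in placement.cells_of.items():
        flower_row_of_cell.ravel()[cells] = flower_index[f]

    # flatten agents
    species_rows, xs, ys, energies = [], [], [], []
    for bee in community.bees:
        nest = nests[bee.species_id]
        if nest is None:
            continue
        r, c = nest
        for _ in range(bee.n_individuals):
            species_rows.append(bee_index[bee.species_id])
            ys.append(r + 0.5)
            xs.append(c + 0.5)
            energies.append(bee.initial_energy)
    species_row = np.array(species_rows, dtype=np.int32)
    x = np.array(xs, dtype=float)
    y = np.array(ys, dtype=float)
    energy = np.array(energies, dtype=float)
    n_agents = species_row.size
    heading = rng.uniform(0.0, 2.0 * np.pi, size=n_agents)
    alive = energy > 0
    path_length = np.zeros(n_agents)
    death_tick = np.full(n_agents, -1, dtype=np.int32)
    initial_energy = energy.copy()

    counts = np.zeros((n_bees, n_flowers), dtype=np.int64)
    turn_sd = np.deg2rad(movement.turn_sd_deg)
    width = float(grid.n_cols)
    height = float(grid.n_rows)
    traj = [np.column_stack((x, y))] if collect_trajectories else None

    tick = 0
    while tick < movement.max_ticks and alive.any():
        tick += 1
        idx = np.flatnonzero(alive)
        turn = rng.normal(0.0, turn_sd, size=idx.size)
        step = rng.normal(movement.step_mean, movement.step_sd, size=idx.size)
        step = np.maximum(step, movement.step_min)
        heading[idx] = np.mod(heading[idx] + turn, 2.0 * np.pi)
        dx = step * np.cos(heading[idx])
        dy = step * np.sin(heading[idx])
        px = x[idx] + dx
        py = y[idx] + dy
        _reflect(px, dx, width)
        _reflect(py, dy, height)
        x[idx] = px
        y[idx] = py
        heading[idx] = np.arctan2(dy, dx)
        path_length[idx] += step
        energy[idx] -= step

        rows = np.minimum(py.astype(np.int64), grid.n_rows - 1)
        cols = np.minimum(px.astype(np.int64), grid.n_cols - 1)
        frow = flower_row_of_cell[rows, cols]
        hit = frow >= 0
        if hit.any():
            b = species_row[idx[hit]]
            f = frow[hit]
            ok = diet_ok[b, f]
            np.add.at(counts, (b[ok], f[ok]), 1)

        died = idx[energy[idx] <= 0]
        alive[died] = False
        death_tick[died] = tick
        if collect_trajectories:
            traj.append(np.column_stack((x, y)))

    visits = VisitMatrix(
        counts=counts,
        bee_ids=community.bee_ids,
        flower_ids=community.flower_ids,
    )
    agents = AgentSummary(
        species_id=np.array([community.bee_ids[s] for s in species_row], dtype=np.int32),
        initial_energy=initial_energy,
        path_length=path_length,
        death_tick=death_tick,
    )
    return SimulationResult(
        visits=visits,
        agents=agents,
        placement=placement,
        nests=nests,
        n_ticks=tick,
        trajectories=np.stack(traj) if collect_trajectories else None,
    )
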