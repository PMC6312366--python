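"""Configuration schema, defaults, and validation.

A single YAML/JSON file can override any of the community, movement and
design defaults; an empty (or absent) config resolves to the default
study conditions: 20 bee species in groups of 9 specialists / 8
generalists / 3 super-generalists with energies 50/100/200 and diet
sizes 1/4/8, 10 individuals per species, 20 flower species of 20 cells
each (half forest, half open), mean step length 2 cells, 150 ticks,
Hurst exponent 0.9, 11 cover levels x 10 replicates.

Every departure from a default is echoed to the log so run provenance
is visible; unknown keys and type mismatches raise ConfigError naming
the offending key.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .experiments import DEFAULT_LEVELS, ExperimentDesign, _seed_int
from .simulator import (
    GROUP_DEFAULTS,
    BeeSpeciesProfile,
    CommunityConfig,
    ConfigError,
    FlowerSpeciesProfile,
    MovementConfig,
    SPECIALIST,
    allocate_diets,
)

__all__ = ["ResolvedConfig", "load_config", "validate_config", "ConfigError"]

logger = logging.getLogger(__name__)

_GROUP_ORDER = (SPECIALIST, "generalist", "super_generalist")

COMMUNITY_DEFAULTS = {
    "groups": {g: dict(GROUP_DEFAULTS[g]) for g in _GROUP_ORDER},
    "n_bee_species": 20,
    "n_individuals": 10,
    "n_flower_species": 20,
    "flower_cells": 20,
}
MOVEMENT_DEFAULTS = {
    "step_mean": 2.0,
    "step_sd": 0.5,
    "step_min": 0.1,
    "turn_sd_deg": 40.0,
    "max_ticks": 150,
}
DESIGN_DEFAULTS = {
    "cover_levels": [round(100 * c) for c in DEFAULT_LEVELS],
    "n_replicates": 10,
    "hurst": 0.9,
    "base_seed": 5,
    "connectivity": 8,
    "connect_threshold": 50.0,
    "sensitivity_reallocations": 0,
}


@dataclass(frozen=True)
class ResolvedConfig:
    community: CommunityConfig
    movement: MovementConfig
    design: ExperimentDesign
    raw: dict


def _merge_section(name: str, defaults: dict, overrides: dict) -> dict:
    unknown = set(overrides) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown keys in section {name!r}: {sorted(unknown)}")
    merged = {**defaults}
    for key, value in overrides.items():
        default = defaults[key]
        if isinstance(default, dict):
            if not isinstance(value, dict):
                raise ConfigError(f"{name}.{key} must be a mapping")
            merged[key] = _merge_section(f"{name}.{key}", default, value)
        else:
            if isinstance(default, (int, float)) and not isinstance(default, bool):
                if not isinstance(value, (int, float)) or isinstance(value, bool):
                    raise ConfigError(f"{name}.{key} must be a number, got {value!r}")
            merged[key] = value
        if merged[key] != default:
            logger.info("config override: %s.%s = %r (default %r)", name, key, value, default)
    return merged


def validate_config(raw: dict | None) -> ResolvedConfig:
    """Fill defaults, check consistency, and build the runnable configs."""
    raw = raw or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(raw) - {"community", "movement", "design"}
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")

    comm = _merge_section("community", COMMUNITY_DEFAULTS, raw.get("community", {}))
    move = _merge_section("movement", MOVEMENT_DEFAULTS, raw.get("movement", {}))
    des = _merge_section("design", DESIGN_DEFAULTS, raw.get("design", {}))

    n_species = sum(comm["groups"][g]["n_species"] for g in _GROUP_ORDER)
    if n_species != comm["n_bee_species"]:
        raise ConfigError(
            f"group species counts sum to {n_species}, "
            f"but n_bee_species is {comm['n_bee_species']}"
        )
    n_flowers = int(comm["n_flower_species"])
    if n_flowers < 2 or n_flowers % 2:
        raise ConfigError("n_flower_species must be an even number >= 2")
    for g in _GROUP_ORDER:
        if comm["groups"][g]["diet_size"] > n_flowers:
            raise ConfigError(
                f"diet size for {g} exceeds the {n_flowers} flower species"
            )

    flowers = tuple(
        FlowerSpeciesProfile(
            flower_id=i,
            guild="forest" if i <= n_flowers // 2 else "open",
            n_cells=int(comm["flower_cells"]),
        )
        for i in range(1, n_flowers + 1)
    )
    bees = []
    sid = 1
    for g in _GROUP_ORDER:
        spec = comm["groups"][g]
        for _ in range(int(spec["n_species"])):
            bees.append(
                BeeSpeciesProfile(
                    species_id=sid,
                    group=g,
                    initial_energy=float(spec["energy"]),
                    diet=(),
                    nest_habitat="forest_only" if g == SPECIALIST else "any",
                    n_individuals=int(comm["n_individuals"]),
                )
            )
            sid += 1

    base_seed = int(des["base_seed"])
    diet_sizes = {g: int(comm["groups"][g]["diet_size"]) for g in _GROUP_ORDER}
    rng = np.random.default_rng(_seed_int(base_seed, 0xD1E7))
    bees = _allocate_with_sizes(bees, flowers, diet_sizes, rng)
    community = CommunityConfig(bees=tuple(bees), flowers=flowers)

    movement = MovementConfig(
        step_mean=float(move["step_mean"]),
        step_sd=float(move["step_sd"]),
        step_min=float(move["step_min"]),
        turn_sd_deg=float(move["turn_sd_deg"]),
        max_ticks=int(move["max_ticks"]),
    )
    levels = tuple(sorted(float(c) / 100.0 for c in des["cover_levels"]))
    design = ExperimentDesign(
        cover_levels=levels,
        n_replicates=int(des["n_replicates"]),
        hurst=float(des["hurst"]),
        base_seed=base_seed,
        community=community,
        movement=movement,
        connectivity=int(des["connectivity"]),
        connect_threshold=float(des["connect_threshold"]),
        sensitivity_reallocations=int(des["sensitivity_reallocations"]),
    )
    return ResolvedConfig(
        community=community,
        movement=movement,
        design=design,
        raw={"community": comm, "movement": move, "design": des},
    )


def _allocate_with_sizes(bees, flowers, diet_sizes, rng):
    """allocate_diets honouring per-group diet sizes from the config."""
    import dataclasses

    flower_ids = np.array([f.flower_id for f in flowers])
    out = []
    for bee in bees:
        k = diet_sizes[bee.group]
        diet = tuple(
            sorted(int(f) for f in rng.choice(flower_ids, size=k, replace=False))
        )
        out.append(dataclasses.replace(bee, diet=diet))
    return out


def load_config(path: str | Path | None) -> ResolvedConfig:
    """Load and validate a YAML or JSON config file (None -> all defaults)."""
    if path is None:
        return validate_config({})
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    return validate_config(raw)
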