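import numpy as np
import pytest

from pollinet import (
    ConfigError,
    LandscapeGrid,
    MovementConfig,
    allocate_diets,
    default_community,
    place_flowers,
    place_nests,
    run_simulation,
)
from pollinet.simulator import GROUP_DEFAULTS, SPECIALIST


def uniform_grid(value, shape=(100, 100)):
    return LandscapeGrid(cover=np.full(shape, value, dtype=np.int8))


class TestAllocateDiets:
    def test_diet_sizes_follow_groups(self, community):
        sizes = sorted(len(b.diet) for b in community.bees)
        assert sizes == [1] * 9 + [4] * 8 + [8] * 3

    def test_max_possible_links(self, community):
        assert sum(len(b.diet) for b in community.bees) <= 9 * 1 + 8 * 4 + 3 * 8

    def test_reallocation_changes_diets(self, community):
        rng = np.random.default_rng(99)
        realloc = allocate_diets(community.bees, community.flowers, rng)
        assert any(a.diet != b.diet for a, b in zip(community.bees, realloc))

    def test_oversized_diet_rejected(self, community):
        few_flowers = community.flowers[:4]
        with pytest.raises(ConfigError):
            allocate_diets(community.bees, few_flowers, np.random.default_rng(0))


class TestPlaceFlowers:
    def test_no_open_habitat_leaves_open_guild_unplaced(self, community):
        placement = place_flowers(
            uniform_grid(1), community.flowers, np.random.default_rng(0)
        )
        for fl in community.flowers:
            expected = 20 if fl.guild == "forest" else 0
            assert placement.n_placed(fl.flower_id) == expected

    def test_half_cover_places_all_cells_uniquely(self, community, half_cover_grid):
        placement = place_flowers(
            half_cover_grid, community.flowers, np.random.default_rng(1)
        )
        all_cells = np.concatenate(list(placement.cells_of.values()))
        assert all_cells.size == 400
        assert np.unique(all_cells).size == 400
        # each placed cell's habitat matches the species' guild
        cover = half_cover_grid.cover.ravel()
        for fl in community.flowers:
            cells = placement.cells_of[fl.flower_id]
            want = 1 if fl.guild == "forest" else 0
            assert (cover[cells] == want).all()

    def test_same_seed_same_placement(self, community, half_cover_grid):
        a = place_flowers(half_cover_grid, community.flowers, np.random.default_rng(7))
        b = place_flowers(half_cover_grid, community.flowers, np.random.default_rng(7))
        assert np.array_equal(a.flower_of_cell, b.flower_of_cell)


class TestPlaceNests:
    def test_no_forest_marks_specialists_absent(self, community):
        nests = place_nests(uniform_grid(0), community.bees, np.random.default_rng(0))
        for bee in community.bees:
            if bee.group == SPECIALIST:
                assert nests[bee.species_id] is None
            else:
                assert nests[bee.species_id] is not None

    def test_full_forest_all_species_nest(self, community):
        nests = place_nests(uniform_grid(1), community.bees, np.random.default_rng(0))
        assert all(v is not None for v in nests.values())

    def test_specialists_always_nest_in_forest(self, community, half_cover_grid):
        cover = half_cover_grid.cover
        for seed in range(200):
            nests = place_nests(
                half_cover_grid, community.bees, np.random.default_rng(seed)
            )
            for bee in community.bees:
                if bee.group == SPECIALIST:
                    r, c = nests[bee.species_id]
                    assert cover[r, c] == 1


class TestRunSimulation:
    def test_deterministic_visit_matrix(self, community, half_cover_grid):
        a = run_simulation(half_cover_grid, community, seed=11)
        b = run_simulation(half_cover_grid, community, seed=11)
        assert np.array_equal(a.visits.counts, b.visits.counts)
        c = run_simulation(half_cover_grid, community, seed=12)
        assert not np.array_equal(a.visits.counts, c.visits.counts)

    def test_diet_closure(self, community, half_cover_grid):
        result = run_simulation(half_cover_grid, community, seed=3)
        counts = result.visits.counts
        for i, bee in enumerate(community.bees):
            allowed = {community.flower_ids.index(f) for f in bee.diet}
            visited = set(np.flatnonzero(counts[i]))
            assert visited <= allowed

    def test_energy_accounting(self, community, half_cover_grid):
        """Each agent's total path length overshoots its energy budget by
        at most one step (it completes the step that kills it)."""
        movement = MovementConfig()
        result = run_simulation(half_cover_grid, community, movement, seed=5)
        agents = result.agents
        assert (agents.death_tick > 0).all()
        max_step = movement.step_mean + 6 * movement.step_sd  # generous bound
        assert (agents.path_length > agents.initial_energy - max_step).all()
        assert (agents.path_length <= agents.initial_energy + max_step).all()
        # dead agents always overshoot their budget
        assert (agents.path_length >= agents.initial_energy).all()

    def test_positions_inside_world(self, community, half_cover_grid):
        result = run_simulation(
            half_cover_grid, community, seed=8, collect_trajectories=True
        )
        xy = result.trajectories
        assert (xy >= 0).all()
        assert (xy[:, :, 0] <= half_cover_grid.n_cols).all()
        assert (xy[:, :, 1] <= half_cover_grid.n_rows).all()

    def test_no_flowers_no_visits(self, community):
        # all-open world: forest flowers unplaced, specialists absent;
        # prune the community to forest flowers only -> nothing to visit
        forest_only_flowers = community.flowers[:10]
        bees = tuple(
            b for b in community.bees if set(b.diet) <= {f.flower_id for f in forest_only_flowers}
        )
        from pollinet import CommunityConfig

        sub = CommunityConfig(bees=bees, flowers=forest_only_flowers)
        if not sub.bees:
            pytest.skip("no bee restricted to forest flowers under this allocation")
        result = run_simulation(uniform_grid(0), sub, seed=2)
        assert result.visits.counts.sum() == 0

    def test_all_dead_within_150_ticks(self, community, half_cover_grid):
        for seed in range(5):
            result = run_simulation(half_cover_grid, community, seed=seed)
            assert 0 < result.all_dead_tick <= 150

    def test_empty_diet_rejected(self, half_cover_grid):
        from dataclasses import replace

        from pollinet import CommunityConfig

        comm = default_community(seed=0)
        bees = (replace(comm.bees[0], diet=()),) + comm.bees[1:]
        broken = CommunityConfig(bees=bees, flowers=comm.flowers)
        with pytest.raises(ConfigError, match="empty diet"):
            run_simulation(half_cover_grid, broken, seed=0)

    def test_specialist_lifetime_matches_truncated_normal(self, half_cover_grid):
        """Expected lifetime = energy / E[step] ticks, with E[step] from
        the step distribution (normal clipped below); Monte-Carlo oracle."""
        movement = MovementConfig()
        rng = np.random.default_rng(0)
        draws = np.maximum(
            rng.normal(movement.step_mean, movement.step_sd, 200_000),
            movement.step_min,
        )
        mean_step = draws.mean()
        energy = GROUP_DEFAULTS[SPECIALIST]["energy"]
        expected_ticks = energy / mean_step

        comm = default_community(seed=1)
        lifetimes = []
        for seed in range(10):
            result = run_simulation(half_cover_grid, comm, movement, seed=seed)
            mask = np.isin(
                result.agents.species_id,
                [b.species_id for b in comm.bees if b.group == SPECIALIST],
            )
            lifetimes.extend(result.agents.death_tick[mask].tolist())
        lifetimes = np.array(lifetimes, dtype=float)
        se = lifetimes.std(ddof=1) / np.sqrt(lifetimes.size)
        # death tick is ceil(lifetime in continuous time): allow the 0.5 bias
        assert abs(lifetimes.mean() - 0.5 - expected_ticks) <= 3 * se + 0.5

    def test_more_individuals_more_visits(self, half_cover_grid):
        """Doubling individuals per species stochastically doubles sampling:
        total visits increase in expectation (mean over 25 seeds)."""
        base = default_community(seed=4, n_individuals=5)
        double = default_community(seed=4, n_individuals=10)
        v1 = np.mean(
            [run_simulation(half_cover_grid, base, seed=s).visits.counts.sum() for s in range(25)]
        )
        v2 = np.mean(
            [run_simulation(half_cover_grid, double, seed=s).visits.counts.sum() for s in range(25)]
        )
        assert v2 > v1
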