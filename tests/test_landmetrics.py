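import numpy as np
import pytest

from oracles import flood_fill_patches, min_pair_distance
from pollinet import LandscapeGrid
from pollinet.landmetrics import (
    area_metrics,
    compute_metrics,
    connect_index,
    label_patches,
    pland,
    shape_metrics,
)


def grid_from(rows):
    return LandscapeGrid(cover=np.array(rows, dtype=np.int8))


def block_grid(n_rows=100, n_cols=100, block=((0, 10), (0, 10))):
    cover = np.zeros((n_rows, n_cols), dtype=np.int8)
    (r0, r1), (c0, c1) = block
    cover[r0:r1, c0:c1] = 1
    return LandscapeGrid(cover=cover)


class TestLabelPatches:
    def test_single_block_area_and_perimeter(self):
        patches = label_patches(block_grid())
        assert len(patches) == 1
        assert patches[0].area_ha == pytest.approx(1.0)
        assert patches[0].perimeter == pytest.approx(400.0)

    def test_diagonal_cells_depend_on_connectivity(self):
        grid = grid_from([[1, 0], [0, 1]])
        assert len(label_patches(grid, connectivity=8)) == 1
        assert len(label_patches(grid, connectivity=4)) == 2

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(7)
        for _ in range(100):
            cover = (rng.random((30, 30)) < rng.uniform(0.2, 0.8)).astype(np.int8)
            grid = LandscapeGrid(cover=cover)
            ours = {
                frozenset(zip(p.rows.tolist(), p.cols.tolist()))
                for p in label_patches(grid, connectivity=connectivity)
            }
            assert ours == set(flood_fill_patches(cover, connectivity))

    def test_patch_ids_ordered_row_major(self):
        grid = grid_from(
            [
                [0, 0, 0, 1],
                [1, 0, 0, 0],
                [0, 0, 0, 0],
                [0, 1, 0, 0],
            ]
        )
        patches = label_patches(grid, connectivity=4)
        firsts = [(int(p.rows[0]), int(p.cols[0])) for p in patches]
        assert firsts == [(0, 3), (1, 0), (3, 1)]
        assert [p.id for p in patches] == [1, 2, 3]

    def test_empty_grid_yields_no_patches(self):
        assert label_patches(grid_from([[0, 0], [0, 0]])) == []


class TestScalarMetrics:
    def test_pland_extremes_and_half(self):
        assert pland(block_grid(block=((0, 100), (0, 100)))) == 100.0
        cover = np.zeros((100, 100), dtype=np.int8)
        cover[:50] = 1
        assert pland(LandscapeGrid(cover=cover)) == 50.0

    def test_area_sum_matches_pland(self, half_cover_grid):
        patches = label_patches(half_cover_grid)
        total_area = sum(p.area for p in patches)
        landscape_area = half_cover_grid.n_cells * half_cover_grid.cell_size**2
        assert total_area == pytest.approx(
            pland(half_cover_grid) / 100 * landscape_area
        )

    def test_area_metrics_hand_computed(self):
        cover = np.zeros((100, 100), dtype=np.int8)
        cover[0:10, 0:10] = 1  # 1 ha
        cover[50:60, 20:50] = 1  # 3 ha
        patches = label_patches(LandscapeGrid(cover=cover))
        mn, am = area_metrics(patches)
        assert mn == pytest.approx(2.0)
        assert am == pytest.approx(2.5)  # (1*1 + 3*3) / 4

    def test_area_metrics_full_cover_and_empty(self):
        mn, am = area_metrics(label_patches(block_grid(block=((0, 100), (0, 100)))))
        assert (mn, am) == (pytest.approx(100.0), pytest.approx(100.0))
        assert area_metrics([]) == (0.0, 0.0)

    def test_equal_patches_have_equal_means(self):
        cover = np.zeros((20, 20), dtype=np.int8)
        cover[0:5, 0:5] = 1
        cover[10:15, 10:15] = 1
        mn, am = area_metrics(label_patches(LandscapeGrid(cover=cover)))
        assert mn == pytest.approx(am)

    def test_shape_index_square_strip_singleton(self):
        square = label_patches(block_grid())[0]
        assert square.shape_index == pytest.approx(1.0)
        strip = label_patches(block_grid(block=((0, 1), (0, 4))))[0]
        assert strip.shape_index == pytest.approx(1.25)  # 0.25 * 100 / 20
        single = label_patches(block_grid(block=((0, 1), (0, 1))))[0]
        assert single.shape_index == pytest.approx(1.0)

    def test_shape_at_least_one_on_random_grids(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            cover = (rng.random((30, 30)) < 0.4).astype(np.int8)
            for p in label_patches(LandscapeGrid(cover=cover)):
                assert p.shape_index >= 1.0 - 1e-12

    def test_shape_metrics_weighting(self):
        cover = np.zeros((100, 100), dtype=np.int8)
        cover[0:10, 0:10] = 1  # square, SHAPE 1.0, 100 cells
        cover[50:51, 0:4] = 1  # strip, SHAPE 1.25, 4 cells
        mn, am = shape_metrics(label_patches(LandscapeGrid(cover=cover)))
        assert mn == pytest.approx((1.0 + 1.25) / 2)
        assert am == pytest.approx((1.0 * 100 + 1.25 * 4) / 104)


class TestConnectIndex:
    def make_patches(self, gaps):
        """1-cell patches along one row, separated by the given gaps (cells)."""
        cols, pos = [], 0
        for gap in gaps:
            cols.append(pos)
            pos += gap + 1
        cover = np.zeros((5, pos + 1), dtype=np.int8)
        for c in cols + [pos]:
            cover[2, c] = 1
        return LandscapeGrid(cover=cover)

    def test_single_patch_scores_zero(self):
        assert connect_index(label_patches(block_grid())) == 0.0
        assert connect_index([]) == 0.0

    def test_two_patches_within_threshold(self):
        grid = self.make_patches([2])  # centres 3 cells -> 30 m apart
        patches = label_patches(grid)
        assert len(patches) == 2
        assert connect_index(patches, threshold=50.0, grid=grid) == 100.0

    def test_three_patches_one_close_pair(self):
        # gaps of 2 and 9 cells: distances 30 m, 100 m, 130 m
        grid = self.make_patches([2, 9])
        patches = label_patches(grid)
        assert len(patches) == 3
        assert connect_index(patches, threshold=50.0, grid=grid) == pytest.approx(
            100.0 / 3
        )

    def test_monotone_in_threshold_and_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(11)
        cover = (rng.random((20, 20)) < 0.25).astype(np.int8)
        grid = LandscapeGrid(cover=cover)
        patches = label_patches(grid)
        cells = [list(zip(p.rows.tolist(), p.cols.tolist())) for p in patches]
        previous = -1.0
        for threshold in (10.0, 30.0, 50.0, 100.0, 300.0):
            ours = connect_index(patches, threshold=threshold, grid=grid)
            n = len(patches)
            close = sum(
                min_pair_distance(cells[i], cells[j]) <= threshold
                for i in range(n)
                for j in range(i + 1, n)
            )
            assert ours == pytest.approx(100.0 * close / (n * (n - 1) / 2))
            assert ours >= previous
            previous = ours


def test_compute_metrics_full_cover_row():
    """A fully forested landscape: one square patch, CONNECT 0."""
    metrics = compute_metrics(block_grid(block=((0, 100), (0, 100))))
    assert metrics.pland == 100.0
    assert metrics.area_mn == pytest.approx(100.0)
    assert metrics.shape_mn == pytest.approx(1.0)
    assert metrics.connect == 0.0
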