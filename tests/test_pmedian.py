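"""Demand grids, the p-median objective, and the selection heuristics."""

from itertools import combinations

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from betasurrogacy import (greedy_pmedian, make_demand_grid,
                           pmedian_objective, select_pmedian,
                           select_pmedian_exact)


def _objective_oracle(selected, grid, coords):
    """Nested-loop distance sums."""
    total = 0.0
    for pt in grid.points:
        total += min(np.hypot(*(pt - coords[s])) for s in selected)
    return total


class TestDemandGrid:
    def test_default_resolution_yields_10000_points(self, rng):
        grid = make_demand_grid(rng.uniform(size=(10, 2)), 100)
        assert grid.m == 100 * 100

    def test_resolution_two_gives_bounding_box_corners(self):
        grid = make_demand_grid(np.array([[0.0, 0.0], [1.0, 1.0]]), 2)
        assert {tuple(p) for p in grid.points} == {(0, 0), (0, 1), (1, 0), (1, 1)}

    def test_grid_spans_site_bounding_box(self, rng):
        coords = rng.normal(size=(17, 2))
        grid = make_demand_grid(coords, 13)
        assert np.allclose(grid.points.min(axis=0), coords.min(axis=0))
        assert np.allclose(grid.points.max(axis=0), coords.max(axis=0))

    def test_zero_extent_rejected(self):
        coords = np.array([[0.0, 1.0], [0.0, 2.0], [0.0, 3.0]])
        with pytest.raises(ValueError, match="zero extent"):
            make_demand_grid(coords, 10)


class TestObjective:
    def test_coincident_point_scores_zero(self):
        coords = np.array([[0.5, 0.5], [2.0, 3.0]])
        grid = make_demand_grid(np.array([[0.0, 0.0], [1.0, 1.0]]), 3)
        # centre demand point coincides with site 0
        assert pmedian_objective([0], grid, coords) == pytest.approx(
            _objective_oracle([0], grid, coords))

    def test_matches_nested_loop_oracle(self, rng):
        coords = rng.uniform(size=(8, 2))
        grid = make_demand_grid(rng.uniform(size=(6, 2)), 5)
        sel = [0, 3, 6]
        assert pmedian_objective(sel, grid, coords) == pytest.approx(
            _objective_oracle(sel, grid, coords), abs=1e-9)

    def test_superset_dominance(self, rng):
        coords = rng.uniform(size=(9, 2))
        grid = make_demand_grid(coords, 7)
        full = pmedian_objective(range(9), grid, coords)
        for p in range(1, 9):
            assert pmedian_objective(range(p), grid, coords) >= full - 1e-12

    def test_empty_selection_rejected(self, rng):
        grid = make_demand_grid(rng.uniform(size=(4, 2)), 3)
        with pytest.raises(ValueError, match="empty"):
            pmedian_objective([], grid, rng.uniform(size=(4, 2)))

    def test_chunking_does_not_change_result(self, rng):
        coords = rng.uniform(size=(20, 2))
        grid = make_demand_grid(coords, 40)
        a = pmedian_objective(range(0, 20, 3), grid, coords, chunk=7)
        c = pmedian_objective(range(0, 20, 3), grid, coords, chunk=10 ** 6)
        assert a == pytest.approx(c, abs=1e-9)


class TestExactSolver:
    def test_p_equals_n_is_the_only_selection(self, rng):
        coords = rng.uniform(size=(4, 2))
        grid = make_demand_grid(coords, 4)
        res = select_pmedian_exact(coords, grid, 4)
        assert res.selected == (0, 1, 2, 3)

    def test_matches_independent_enumeration(self, rng):
        coords = rng.uniform(size=(6, 2))
        grid = make_demand_grid(coords, 5)
        res = select_pmedian_exact(coords, grid, 2)
        D = cdist(grid.points, coords)
        best = min((D[:, list(s)].min(axis=1).sum(), s)
                   for s in combinations(range(6), 2))
        assert res.objective == pytest.approx(best[0], abs=1e-9)
        assert res.selected == best[1]

    def test_optimum_nonincreasing_in_p(self, rng):
        coords = rng.uniform(size=(7, 2))
        grid = make_demand_grid(coords, 6)
        objs = [select_pmedian_exact(coords, grid, p).objective
                for p in range(1, 8)]
        assert all(a >= b - 1e-12 for a, b in zip(objs, objs[1:]))

    def test_oversized_instance_rejected(self, rng):
        coords = rng.uniform(size=(40, 2))
        grid = make_demand_grid(coords, 4)
        with pytest.raises(ValueError, match="combinations"):
            select_pmedian_exact(coords, grid, 15, max_combinations=100)


class TestHeuristic:
    def test_p_equals_n_selects_everything(self, rng):
        coords = rng.uniform(size=(6, 2))
        grid = make_demand_grid(coords, 5)
        res = select_pmedian(coords, grid, 6, seed=0)
        assert res.selected == tuple(range(6))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exact_optimum_on_small_instances(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(5, 13))
        p = int(rng.integers(1, 5))
        coords = rng.uniform(size=(n, 2))
        grid = make_demand_grid(rng.uniform(size=(8, 2)), 5)
        heur = select_pmedian(coords, grid, p, seed=seed)
        exact = select_pmedian_exact(coords, grid, p)
        assert heur.objective == pytest.approx(exact.objective, abs=1e-9)

    def test_center_site_wins_for_p1(self):
        coords = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0],
                           [0.5, 0.5]])
        grid = make_demand_grid(coords[:4], 21)
        res = select_pmedian(coords, grid, 1, seed=0)
        assert res.selected == (4,)

    def test_invalid_p_rejected(self, rng):
        coords = rng.uniform(size=(5, 2))
        grid = make_demand_grid(coords, 4)
        with pytest.raises(ValueError):
            select_pmedian(coords, grid, 0)
        with pytest.raises(ValueError):
            select_pmedian(coords, grid, 6)

    def test_never_worse_than_greedy_construction(self):
        for seed in range(8):
            rng = np.random.default_rng(2000 + seed)
            coords = rng.uniform(size=(20, 2))
            grid = make_demand_grid(coords, 12)
            heur = select_pmedian(coords, grid, 4, seed=seed)
            greedy = greedy_pmedian(coords, grid, 4)
            assert heur.objective <= greedy.objective + 1e-9

    def test_objective_nonincreasing_in_n_starts(self):
        rng = np.random.default_rng(77)
        coords = rng.uniform(size=(25, 2))
        grid = make_demand_grid(coords, 15)
        objs = [select_pmedian(coords, grid, 5, n_starts=k, seed=5).objective
                for k in (1, 4, 16, 32)]
        assert all(a >= b - 1e-9 for a, b in zip(objs, objs[1:]))

    def test_deterministic_under_seed(self, rng):
        coords = rng.uniform(size=(15, 2))
        grid = make_demand_grid(coords, 10)
        a = select_pmedian(coords, grid, 4, seed=9)
        c = select_pmedian(coords, grid, 4, seed=9)
        assert a.selected == c.selected and a.objective == c.objective

    def test_reported_objective_matches_recomputation(self, rng):
        coords = rng.uniform(size=(12, 2))
        grid = make_demand_grid(coords, 9)
        res = select_pmedian(coords, grid, 3, seed=2)
        assert res.objective == pmedian_objective(res.selected, grid, coords)
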