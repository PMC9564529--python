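import numpy as np
import pytest

from econeeds.landscape_core import AreaVector, LandUseGrid, class_areas
from econeeds.cars import (
    CarsParams,
    TransitionRules,
    adaptive_coefficient,
    allocate,
    neighborhood_effect,
    overall_probability,
    overall_probability_seed,
    run_scenario,
)


class TestNeighborhoodEffect:
    def test_saturated_neighborhood(self):
        grid = LandUseGrid(np.full((5, 5), 3))
        omega = neighborhood_effect(grid, 3)
        assert omega[2, 2] == pytest.approx(1.0)

    def test_isolated_cell_zero_at_distance(self):
        codes = np.ones((7, 7), dtype=int)
        codes[3, 3] = 2
        omega = neighborhood_effect(LandUseGrid(codes), 2)
        assert omega[0, 0] == 0.0
        assert omega[3, 3] == 0.0  # center excluded
        assert omega[3, 4] == pytest.approx(1 / 8)

    def test_edge_cells_use_clipped_window(self):
        grid = LandUseGrid(np.full((4, 4), 5))
        omega = neighborhood_effect(grid, 5)
        assert omega[0, 0] == pytest.approx(1.0)  # 3 of 3 in-bounds neighbors

    def test_matches_per_cell_loop(self, rng):
        codes = rng.integers(1, 7, size=(10, 10))
        grid = LandUseGrid(codes)
        for k in (1, 2, 6):
            omega = neighborhood_effect(grid, k, 3)
            for i in range(10):
                for j in range(10):
                    win = codes[max(0, i - 1):i + 2, max(0, j - 1):j + 2]
                    count = (win == k).sum() - (codes[i, j] == k)
                    denom = win.size - 1
                    assert omega[i, j] == pytest.approx(count / denom)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            neighborhood_effect(LandUseGrid(np.ones((4, 4), dtype=int)), 1, 4)


class TestAdaptiveCoefficient:
    def test_shrinking_gap_keeps_d(self):
        assert adaptive_coefficient(2.0, 100, 95, 90) == 2.0

    def test_met_demand_keeps_d(self):
        d = adaptive_coefficient(1.5, 100, 100, 98)
        assert d == 1.5
        assert adaptive_coefficient(d, 100, 100, 100) == 1.5

    def test_growing_deficit_scales_d(self):
        # gap doubles from 5 to 10 -> D doubles (pre-clip)
        assert adaptive_coefficient(1.0, 100, 90, 95) == pytest.approx(2.0)

    def test_clipped_to_bounds(self):
        assert adaptive_coefficient(8.0, 100, 0, 50) == 10.0
        assert adaptive_coefficient(0.2, 100, 150, 110) == pytest.approx(
            np.clip(0.2 * 5, 0.1, 10.0)
        )


class TestOverallProbability:
    def test_elementwise_product(self):
        P = np.full((2, 2), 0.5)
        omega = np.full((2, 2), 0.5)
        np.testing.assert_allclose(overall_probability(P, omega, 1.0), 0.25)

    def test_zero_neighborhood_zero(self):
        P = np.full((2, 2), 0.9)
        np.testing.assert_allclose(overall_probability(P, np.zeros((2, 2)), 2.0), 0.0)

    def test_seed_branch_arithmetic(self):
        rng = np.random.default_rng(11)
        P = rng.random((4, 4))
        r = rng.random((4, 4))
        out = overall_probability_seed(P, r, 0.5, 1.5)
        expected = np.empty((4, 4))
        for i in range(4):
            for j in range(4):
                expected[i, j] = P[i, j] * r[i, j] * 0.5 * 1.5
        np.testing.assert_allclose(out, expected)


def _uniform_probs(shape, value=0.5):
    return {k: np.full(shape, value) for k in range(1, 7)}


def _toy_grid(rng, shape=(20, 20)):
    codes = rng.integers(1, 5, size=shape)  # ecological classes only
    codes[0, :2] = 5
    codes[0, 2:4] = 6
    return LandUseGrid(codes)


class TestAllocate:
    def test_null_allocation_is_identity(self, rng):
        grid = _toy_grid(rng)
        demand = class_areas(grid)
        out = allocate(grid, _uniform_probs(grid.shape), demand,
                       params=CarsParams(seed=0))
        np.testing.assert_array_equal(out.codes, grid.codes)

    def test_moves_ten_cells_between_classes(self, rng):
        grid = _toy_grid(rng)
        demand = class_areas(grid).area_km2.copy()
        demand[1] += 10  # forest gains
        demand[2] -= 10  # grass sheds
        out, diag = allocate(
            grid, _uniform_probs(grid.shape), AreaVector(demand),
            params=CarsParams(seed=1, demand_tol_frac=0.0), full_output=True,
        )
        np.testing.assert_allclose(class_areas(out).area_km2, demand)
        assert int((out.codes != grid.codes).sum()) == 10

    def test_area_conserved_every_iteration(self, rng):
        grid = _toy_grid(rng)
        demand = class_areas(grid).area_km2.copy()
        demand[[0, 1, 2, 3]] += [15, -10, -15, 10]
        _, diag = allocate(
            grid, _uniform_probs(grid.shape), AreaVector(demand),
            params=CarsParams(seed=2), full_output=True,
        )
        totals = diag["area_log_cells"].sum(axis=1)
        assert (totals == totals[0]).all()

    def test_demanded_growth_of_builtup_errors(self, rng):
        grid = _toy_grid(rng)
        demand = class_areas(grid).area_km2.copy()
        demand[4] += 5
        demand[2] -= 5
        with pytest.raises(ValueError, match="class 5"):
            allocate(grid, _uniform_probs(grid.shape), AreaVector(demand),
                     params=CarsParams(seed=0, demand_tol_frac=0.0))

    def test_frozen_cells_bit_identical(self, rng):
        grid = _toy_grid(rng)
        frozen = np.zeros(grid.shape, bool)
        frozen[5:15, 5:15] = True
        rules = TransitionRules(frozen_mask=frozen)
        demand = class_areas(grid).area_km2.copy()
        demand[[1, 2]] += [20, -20]
        out = allocate(grid, _uniform_probs(grid.shape), AreaVector(demand),
                       rules=rules, params=CarsParams(seed=3))
        np.testing.assert_array_equal(out.codes[frozen], grid.codes[frozen])

    def test_deterministic_under_seed(self, rng):
        grid = _toy_grid(rng)
        demand = class_areas(grid).area_km2.copy()
        demand[[0, 1]] += [12, -12]
        probs = {k: np.random.default_rng(k).random(grid.shape)
                 for k in range(1, 7)}
        a = allocate(grid, probs, AreaVector(demand), params=CarsParams(seed=9))
        b = allocate(grid, probs, AreaVector(demand), params=CarsParams(seed=9))
        np.testing.assert_array_equal(a.codes, b.codes)

    def test_no_seeding_means_growth_only_near_patches(self):
        # with expansion_coefficient 0, class 4 may only grow adjacent to
        # existing water cells
        codes = np.full((15, 15), 2)
        codes[7, 7] = 4
        grid = LandUseGrid(codes)
        demand = class_areas(grid).area_km2.copy()
        demand[[3, 1]] += [8, -8]
        out = allocate(
            grid, _uniform_probs(grid.shape, 0.8), AreaVector(demand),
            params=CarsParams(seed=4, expansion_coefficient=0.0,
                              demand_tol_frac=0.0),
        )
        water = np.argwhere(out.codes == 4)
        # all water cells connected to the initial seed cell's patch
        from scipy import ndimage

        labels, n = ndimage.label(out.codes == 4, structure=np.ones((3, 3)))
        assert n == 1
        assert len(water) == 9

    def test_demand_total_mismatch_rejected(self, rng):
        grid = _toy_grid(rng)
        demand = class_areas(grid).area_km2 * 1.5
        with pytest.raises(ValueError, match="total"):
            allocate(grid, _uniform_probs(grid.shape), AreaVector(demand))


class TestRunScenario:
    def test_converges_to_demand_and_reports(self, small_landscape):
        t0, t1, drivers, _ = small_landscape
        demand = class_areas(t1).area_km2.copy()
        demand[[0, 1, 2]] += [30, -50, 20]
        out, diag = run_scenario(
            t0, t1, drivers, AreaVector(demand),
            params=CarsParams(seed=5), n_per_class=500, M=10,
        )
        tol = 0.001 * class_areas(t1).total
        assert np.abs(diag["final_areas"].area_km2 - demand).max() <= tol
        assert -1 <= diag["kappa_vs_base"] <= 1
        assert diag["iterations"] >= 1

    def test_reproducible(self, small_landscape):
        t0, t1, drivers, _ = small_landscape
        demand = class_areas(t1).area_km2.copy()
        demand[[1, 2]] += [-25, 25]
        a, _ = run_scenario(t0, t1, drivers, AreaVector(demand),
                            params=CarsParams(seed=6), n_per_class=300, M=10)
        b, _ = run_scenario(t0, t1, drivers, AreaVector(demand),
                            params=CarsParams(seed=6), n_per_class=300, M=10)
        np.testing.assert_array_equal(a.codes, b.codes)
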