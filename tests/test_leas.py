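import numpy as np
import pytest

from econeeds.landscape_core import NEEDS_GROUPS, DriverStack, LandUseGrid
from econeeds.leas import (
    ExpansionSamples,
    driver_importance,
    extract_expansion,
    fit_all_classes,
    fit_growth_model,
    growth_probability,
    sample_training,
)


def _stack(shape, names=("d1", "d2"), seed=0):
    rng = np.random.default_rng(seed)
    return DriverStack(
        {n: rng.random(shape) for n in names},
        needs_group={n: ("material",) for n in names},
    )


class TestExtractExpansion:
    def test_no_change_gives_no_positives(self, rng):
        grid = LandUseGrid(rng.integers(1, 7, size=(10, 10)))
        for k in range(1, 7):
            exp = extract_expansion(grid, grid, k)
            assert (exp != 1).all()
            # cells already k are ineligible, the rest eligible negatives
            assert ((exp == -1) == (grid.codes == k)).all()

    def test_single_cell_flip(self):
        t0 = LandUseGrid(np.ones((5, 5), dtype=int))
        t1c = t0.codes.copy()
        t1c[2, 2] = 2
        t1 = LandUseGrid(t1c)
        assert (extract_expansion(t0, t1, 2) == 1).sum() == 1
        assert (extract_expansion(t0, t1, 1) == 1).sum() == 0

    def test_matches_per_cell_loop(self):
        rng = np.random.default_rng(5)
        c0 = rng.integers(1, 7, size=(12, 12))
        c1 = rng.integers(1, 7, size=(12, 12))
        t0, t1 = LandUseGrid(c0), LandUseGrid(c1)
        for k in (1, 4, 6):
            exp = extract_expansion(t0, t1, k)
            for i in range(12):
                for j in range(12):
                    if c0[i, j] == k:
                        assert exp[i, j] == -1
                    else:
                        assert exp[i, j] == (1 if c1[i, j] == k else 0)

    def test_positives_partition_changed_cells(self, rng):
        c0 = rng.integers(1, 7, size=(20, 20))
        c1 = c0.copy()
        flip = rng.random(c0.shape) < 0.2
        c1[flip] = 1 + (c0[flip] % 6)
        t0, t1 = LandUseGrid(c0), LandUseGrid(c1)
        total = sum(
            int((extract_expansion(t0, t1, k) == 1).sum()) for k in range(1, 7)
        )
        assert total == int((c0 != c1).sum())

    def test_shape_mismatch_rejected(self, rng):
        a = LandUseGrid(rng.integers(1, 7, size=(5, 5)))
        b = LandUseGrid(rng.integers(1, 7, size=(6, 6)))
        with pytest.raises(ValueError):
            extract_expansion(a, b, 1)


class TestSampleTraining:
    def _expansion(self, n_pos=40, n_neg=400, shape=(30, 30), seed=0):
        rng = np.random.default_rng(seed)
        exp = np.full(shape, -1, dtype=np.int8)
        cells = rng.choice(shape[0] * shape[1], n_pos + n_neg, replace=False)
        exp.ravel()[cells[:n_pos]] = 1
        exp.ravel()[cells[n_pos:]] = 0
        return exp

    def test_balanced_capped_by_positives(self):
        exp = self._expansion(n_pos=40)
        s = sample_training(exp, _stack(exp.shape), n_per_class=100, seed=1)
        assert len(s.y) == 80
        assert s.y.sum() == 40

    def test_deterministic_under_seed(self):
        exp = self._expansion()
        a = sample_training(exp, _stack(exp.shape), 50, seed=7)
        b = sample_training(exp, _stack(exp.shape), 50, seed=7)
        np.testing.assert_array_equal(a.cells, b.cells)
        np.testing.assert_array_equal(a.X, b.X)

    def test_uniform_label_frequency_tracks_map(self):
        exp = self._expansion(n_pos=300, n_neg=300, shape=(40, 40))
        s = sample_training(exp, _stack((40, 40)), 400, strategy="uniform", seed=2)
        # true positive rate 0.5; binomial 3-sigma ~ 0.075 at n=400
        assert s.y.mean() == pytest.approx(0.5, abs=0.08)

    def test_zero_positives_errors_with_class(self):
        exp = np.zeros((10, 10), dtype=np.int8)
        with pytest.raises(ValueError, match="class 3"):
            sample_training(exp, _stack((10, 10)), 10, k=3)

    def test_ineligible_cells_never_sampled(self):
        exp = self._expansion()
        s = sample_training(exp, _stack(exp.shape), 500, seed=3)
        assert (exp.ravel()[s.cells] != -1).all()


def _separable_samples(n=200, seed=0):
    # margin around the d1 = 0.5 boundary so every bootstrap tree separates
    rng = np.random.default_rng(seed)
    X = rng.random((n, 2))
    X[:, 0] = np.where(X[:, 0] > 0.5, 0.6 + 0.4 * X[:, 0], 0.4 * X[:, 0])
    y = (X[:, 0] > 0.5).astype(np.int8)
    return ExpansionSamples(X=X, y=y, cells=np.arange(n),
                            driver_names=["d1", "d2"], k=2)


class TestGrowthModel:
    def test_separable_training_probabilities(self):
        s = _separable_samples()
        model = fit_growth_model(s, M=20, seed=0)
        stack = DriverStack(
            {"d1": s.X[:, 0].reshape(1, -1), "d2": s.X[:, 1].reshape(1, -1)},
            needs_group={"d1": ("material",), "d2": ("material",)},
        )
        p = growth_probability(model, stack).ravel()
        # bagging leaves a few out-of-bag votes astray even on separable data
        assert (p[s.y == 1] >= 0.85).all()
        assert (p[s.y == 0] <= 0.15).all()
        assert p[s.y == 1].mean() > 0.97 and p[s.y == 0].mean() < 0.03

    def test_single_tree_votes_are_binary(self):
        model = fit_growth_model(_separable_samples(), M=1, seed=0)
        stack = _stack((10, 10), seed=1)
        p = growth_probability(model, stack)
        assert set(np.unique(p)) <= {0.0, 1.0}

    def test_prediction_is_vote_count_over_M(self):
        model = fit_growth_model(_separable_samples(), M=15, seed=3)
        stack = _stack((8, 8), seed=2)
        p = growth_probability(model, stack)
        X = stack.matrix(model.driver_names)
        votes = np.zeros(len(X))
        for tree in model.forest.estimators_:
            votes += (tree.predict(X) == 1).astype(int)
        np.testing.assert_allclose(p.ravel(), votes / 15)

    def test_probability_bounded(self, rng):
        model = fit_growth_model(_separable_samples(seed=4), M=10, seed=4)
        for seed in range(3):
            p = growth_probability(model, _stack((20, 20), seed=seed))
            assert np.nanmin(p) >= 0 and np.nanmax(p) <= 1

    def test_single_label_rejected(self):
        s = _separable_samples()
        s = ExpansionSamples(X=s.X, y=np.ones_like(s.y), cells=s.cells,
                             driver_names=s.driver_names, k=1)
        with pytest.raises(ValueError, match="single label"):
            fit_growth_model(s)

    def test_missing_driver_rejected(self):
        model = fit_growth_model(_separable_samples(), M=5, seed=0)
        stack = DriverStack({"d1": np.zeros((4, 4))},
                            needs_group={"d1": ("material",)})
        with pytest.raises(ValueError, match="missing"):
            growth_probability(model, stack)

    def test_surface_invariant_to_driver_insertion_order(self):
        model = fit_growth_model(_separable_samples(), M=10, seed=1)
        rng = np.random.default_rng(0)
        d1, d2 = rng.random((6, 6)), rng.random((6, 6))
        groups = {"d1": ("material",), "d2": ("material",)}
        a = growth_probability(model, DriverStack({"d1": d1, "d2": d2}, groups))
        b = growth_probability(model, DriverStack({"d2": d2, "d1": d1}, groups))
        np.testing.assert_array_equal(a, b)


class TestDriverImportance:
    def test_importances_normalized(self):
        model = fit_growth_model(_separable_samples(), M=20, seed=0)
        per_driver, _ = driver_importance(model)
        assert per_driver.sum() == pytest.approx(1.0)
        assert per_driver["d1"] > per_driver["d2"]

    def test_group_contributions_sum_to_one_with_split_drivers(self):
        model = fit_growth_model(_separable_samples(), M=20, seed=0)
        groups = {"d1": ("security", "material"), "d2": ("spiritual",)}
        _, per_group = driver_importance(model, groups)
        assert per_group.sum() == pytest.approx(1.0)
        assert set(per_group.index) == {"security", "material", "spiritual"}

    def test_dominant_synthetic_driver_recovered(self, small_landscape):
        t0, t1, drivers, _ = small_landscape
        exp = extract_expansion(t0, t1, 1)
        s = sample_training(exp, drivers, 2000, seed=0, k=1)
        model = fit_growth_model(s, M=50, seed=0)
        per_driver, per_group = driver_importance(model, NEEDS_GROUPS)
        # class 1's generator weight is 3x on dem
        assert per_driver.idxmax() == "dem"
        assert per_group.sum() == pytest.approx(1.0)


class TestFitAllClasses:
    def test_surfaces_for_all_classes(self, small_landscape):
        t0, t1, drivers, _ = small_landscape
        probs = fit_all_classes(t0, t1, drivers, n_per_class=500, M=10, seed=0)
        assert set(probs) == set(range(1, 7))
        for p in probs.values():
            assert p.shape == t0.shape
            assert np.nanmin(p) >= 0 and np.nanmax(p) <= 1
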