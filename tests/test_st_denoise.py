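"""Spot graphs, SSR smoothing, imputation baselines, scarcity experiment."""

import numpy as np
import pytest
from scipy.sparse.csgraph import connected_components

from spectropath import (
    DuplicatePositionsError,
    SpotFieldParams,
    SpotTable,
    build_spot_graph,
    generate_spot_field,
    knn_impute,
    rbf_impute,
    scarcity_experiment,
    ssr_smooth,
    synthesize_spots,
)


@pytest.fixture(scope="module")
def hex_field():
    return generate_spot_field(SpotFieldParams(n_spots=400, seed=0))


class TestSpotGraph:
    def test_hex_interior_six_neighbors(self, hex_field):
        spots, _ = hex_field
        g = build_spot_graph(spots.positions, k=6)
        center = np.argmin(((spots.positions - spots.positions.mean(axis=0)) ** 2).sum(axis=1))
        assert g.weights[center].getnnz() == 6

    def test_two_spots_single_edge(self):
        g = build_spot_graph(np.array([[0.0, 0.0], [3.0, 0.0]]), k=1, sigma=2.0)
        assert g.weights.nnz == 2
        assert g.weights[0, 1] == pytest.approx(np.exp(-9 / 8))

    def test_connected_on_fixture_grid(self, hex_field):
        spots, _ = hex_field
        g = build_spot_graph(spots.positions)
        ncomp, _ = connected_components(g.weights, directed=False)
        assert ncomp == 1

    def test_rows_sum_to_one(self, hex_field):
        spots, _ = hex_field
        g = build_spot_graph(spots.positions)
        assert np.allclose(np.asarray(g.smoother.sum(axis=1)).ravel(), 1.0, atol=1e-9)

    def test_duplicate_positions_raise(self):
        with pytest.raises(DuplicatePositionsError):
            build_spot_graph(np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0]]))


class TestSSRSmooth:
    def test_constant_gene_is_fixed_point(self, hex_field):
        spots, _ = hex_field
        g = build_spot_graph(spots.positions)
        const = np.full((spots.n_spots, 2), 3.7)
        assert np.allclose(ssr_smooth(g, const, steps=5), 3.7, atol=1e-9)

    def test_zero_steps_identity(self, hex_field):
        spots, _ = hex_field
        g = build_spot_graph(spots.positions)
        assert np.array_equal(ssr_smooth(g, spots.expression, steps=0), spots.expression)

    def test_values_stay_within_column_range(self, hex_field):
        spots, _ = hex_field
        g = build_spot_graph(spots.positions)
        sm = ssr_smooth(g, spots.expression, steps=4)
        assert (sm.min(axis=0) >= spots.expression.min(axis=0) - 1e-12).all()
        assert (sm.max(axis=0) <= spots.expression.max(axis=0) + 1e-12).all()

    def test_spread_contracts_monotonically(self, hex_field):
        spots, _ = hex_field
        g = build_spot_graph(spots.positions)
        X = spots.expression
        spreads = []
        for _ in range(8):
            spreads.append((X.max(axis=0) - X.min(axis=0)).copy())
            X = ssr_smooth(g, X, steps=1)
        spreads = np.array(spreads)
        assert (np.diff(spreads, axis=0) <= 1e-12).all()

    @pytest.mark.parametrize("seed", range(10))
    def test_smoothing_denoises_toward_ground_truth(self, seed):
        spots, truth = generate_spot_field(SpotFieldParams(n_spots=200, seed=seed))
        g = build_spot_graph(spots.positions)
        sm = ssr_smooth(g, spots.expression, steps=3)
        assert ((sm - truth) ** 2).mean() < ((spots.expression - truth) ** 2).mean()


class TestSynthesizeSpots:
    def test_linear_field_exact_at_midpoints(self):
        pos = np.array([[float(x), float(y)] for x in range(5) for y in range(5)])
        g = build_spot_graph(pos, k=4)
        f = pos[:, 0:1]  # f(x, y) = x
        mini = synthesize_spots(g, pos, f)
        assert np.abs(mini.expression[:, 0] - mini.positions[:, 0]).max() < 1e-9

    def test_count_equals_edges_and_nonnegative(self, hex_field):
        spots, _ = hex_field
        g = build_spot_graph(spots.positions)
        mini = synthesize_spots(g, spots.positions, spots.expression)
        assert mini.n_spots == g.edges.shape[0]
        assert (mini.expression >= 0).all()


class TestImputers:
    def test_knn_exact_copy_at_observed_position(self):
        pos = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        X = np.array([[1.0], [2.0], [3.0]])
        pred = knn_impute(pos, X, np.array([[1.0, 0.0]]), k=1)
        assert pred[0, 0] == 2.0

    def test_knn_equidistant_mean(self):
        pos = np.array([[-1.0, 0.0], [1.0, 0.0]])
        X = np.array([[2.0], [6.0]])
        pred = knn_impute(pos, X, np.array([[0.0, 0.0]]), k=2)
        assert pred[0, 0] == pytest.approx(4.0)

    def test_knn_matches_brute_force(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 10, size=(50, 2))
        X = rng.random((50, 3))
        targets = rng.uniform(0, 10, size=(20, 2))
        k = 5
        pred = knn_impute(pos, X, targets, k=k)
        for t in range(20):
            d = np.sqrt(((pos - targets[t]) ** 2).sum(axis=1))
            nearest = np.argsort(d)[:k]
            w = 1.0 / d[nearest]
            expect = (w / w.sum()) @ X[nearest]
            assert np.allclose(pred[t], expect, atol=1e-10)

    def test_rbf_limits(self):
        rng = np.random.default_rng(1)
        pos = rng.uniform(0, 5, size=(20, 2))
        X = rng.random((20, 2))
        t = np.array([[2.0, 2.0]])
        near = rbf_impute(pos, X, t, sigma=1e-4)
        nearest = np.argmin(((pos - t[0]) ** 2).sum(axis=1))
        assert np.allclose(near[0], X[nearest], atol=1e-8)
        wide = rbf_impute(pos, X, t, sigma=1e6)
        assert np.allclose(wide[0], X.mean(axis=0), atol=1e-6)

    def test_rbf_matches_dense_kernel(self):
        rng = np.random.default_rng(2)
        pos = rng.uniform(0, 10, size=(50, 2))
        X = rng.random((50, 2))
        targets = rng.uniform(0, 10, size=(10, 2))
        sigma = 1.5
        pred = rbf_impute(pos, X, targets, sigma=sigma)
        d2 = ((targets[:, None] - pos[None]) ** 2).sum(-1)
        w = np.exp(-d2 / (2 * sigma**2))
        expect = (w / w.sum(axis=1, keepdims=True)) @ X
        assert np.allclose(pred, expect, atol=1e-10)

    def test_constant_field_exactly_interpolated_by_all(self):
        rng = np.random.default_rng(3)
        pos = rng.uniform(0, 8, size=(30, 2))
        X = np.full((30, 2), 1.25)
        t = rng.uniform(0, 8, size=(5, 2))
        from spectropath import ssr_predict

        for pred in (
            knn_impute(pos, X, t, k=4),
            rbf_impute(pos, X, t, sigma=1.0),
            ssr_predict(pos, X, t),
        ):
            assert np.allclose(pred, 1.25, atol=1e-9)


class TestScarcityExperiment:
    def test_metric_table_shape(self, hex_field):
        spots, _ = hex_field
        table = scarcity_experiment(spots, fraction=0.25, n_shuffles=2, seed=0)
        assert list(table.columns) == ["PCC", "MAE", "RMSE", "R2"]
        assert sorted(table.index) == ["RBFxy", "SSR", "kNNxy"]

    def test_easy_regime_near_perfect(self):
        spots, truth = generate_spot_field(
            SpotFieldParams(n_spots=300, noise_sd=0.0, seed=1)
        )
        table = scarcity_experiment(spots, fraction=0.9, n_shuffles=2, seed=0)
        assert (table["PCC"] > 0.95).all()

    def test_invariant_to_gene_order(self, hex_field):
        spots, _ = hex_field
        perm = np.random.default_rng(4).permutation(spots.expression.shape[1])
        shuffled = SpotTable(positions=spots.positions, expression=spots.expression[:, perm])
        t1 = scarcity_experiment(spots, n_shuffles=2, seed=3)
        t2 = scarcity_experiment(shuffled, n_shuffles=2, seed=3)
        assert np.allclose(t1.to_numpy(), t2.to_numpy(), atol=1e-10)

    def test_bad_fraction_rejected(self, hex_field):
        spots, _ = hex_field
        with pytest.raises(ValueError):
            scarcity_experiment(spots, fraction=1.0)
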