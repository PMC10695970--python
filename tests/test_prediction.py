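"""Timepoint splitting, predictor construction, ridge and PCR."""

import numpy as np
import pytest
from scipy import stats

from obliquescale.core import CellTable
from obliquescale.prediction import (
    RegressionConfig,
    SplitScheme,
    _ridge_solve,
    pcr_dimensionality,
    predict_brainwide,
    ridge_predict,
    sample_predictors,
    spatial_shuffle,
    split_timepoints,
    variance_weighted_r2,
    voxelize_grid,
)
from obliquescale.synthetic import (
    PopulationConfig,
    generate_cell_positions,
    generate_population_activity,
)


@pytest.fixture(scope="module")
def latent10_population():
    """300 cells driven by 10 strong latent factors, low noise."""
    cfg = PopulationConfig(
        n_cells=300,
        duration=900.0,
        n_latent=10,
        noise_sd=2.0,
        private_fraction=0.0,
        brain_extent=(600.0, 400.0, 300.0),
        seed=21,
    )
    truth = generate_population_activity(generate_cell_positions(cfg), cfg)
    return truth, truth.to_cell_table()


class TestSplitTimepoints:
    def test_single_block_layout(self):
        s = split_timepoints(300, rate=1.0)
        np.testing.assert_array_equal(s.train, np.arange(0, 180))
        np.testing.assert_array_equal(s.validation, np.arange(180, 240))
        np.testing.assert_array_equal(s.test, np.arange(240, 300))

    def test_default_duration_fractions(self):
        s = split_timepoints(2280, rate=1.0)
        assert s.train.size / 2280 == pytest.approx(0.6, abs=0.01)
        assert s.validation.size / 2280 == pytest.approx(0.2, abs=0.01)
        assert s.test.size / 2280 == pytest.approx(0.2, abs=0.01)

    @pytest.mark.parametrize("T", [300, 301, 555, 1234, 2280])
    def test_disjoint_and_complete(self, T):
        s = split_timepoints(T, rate=1.0)
        allidx = np.concatenate([s.train, s.validation, s.test])
        np.testing.assert_array_equal(np.sort(allidx), np.arange(T))

    def test_too_short(self):
        with pytest.raises(ValueError):
            split_timepoints(200, rate=1.0)

    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            SplitScheme(train=np.arange(5), validation=np.arange(4, 8), test=np.arange(8, 10))


class TestVoxelizeGrid:
    def test_giant_voxel_is_global_mean(self, rng):
        pos = rng.uniform(0, 100, (10, 3))
        dff = rng.normal(size=(40, 10))
        ps = voxelize_grid(CellTable(positions=pos, dff=dff), 1e4)
        assert ps.n_predictors == 1
        np.testing.assert_allclose(ps.traces[:, 0], dff.mean(axis=1))

    def test_known_binning(self):
        pos = np.array([[10.0, 10, 10], [20, 10, 10], [110, 10, 10]])
        dff = np.arange(12, dtype=float).reshape(4, 3)
        ps = voxelize_grid(CellTable(positions=pos, dff=dff), 100.0)
        assert ps.n_predictors == 2
        members = sorted(tuple(m) for m in ps.member_ids)
        assert members == [(0, 1), (2,)]
        # bin [0,100) holds cells 0,1; bin [100,200) holds cell 2
        cols = {tuple(m): i for i, m in enumerate(ps.member_ids)}
        np.testing.assert_allclose(ps.traces[:, cols[(0, 1)]], dff[:, :2].mean(axis=1))
        np.testing.assert_allclose(ps.traces[:, cols[(2,)]], dff[:, 2])

    def test_half_open_origin_anchored_bins(self):
        pos = np.array([[0.0, 0, 0], [99.999, 0, 0], [100.0, 0, 0]])
        dff = np.zeros((5, 3))
        ps = voxelize_grid(CellTable(positions=pos, dff=dff), 100.0)
        members = sorted(tuple(m) for m in ps.member_ids)
        assert members == [(0, 1), (2,)]


class TestSamplePredictors:
    def test_full_count_identity(self, rng):
        pos = rng.uniform(0, 100, (8, 3))
        dff = rng.normal(size=(30, 8))
        table = CellTable(positions=pos, dff=dff)
        ps = sample_predictors(table, 8, seed=0)
        assert ps.n_predictors == 8
        np.testing.assert_allclose(np.sort(ps.traces.sum(axis=0)), np.sort(dff.sum(axis=0)))

    def test_reproducible(self, rng):
        table = CellTable(positions=rng.uniform(0, 100, (20, 3)), dff=rng.normal(size=(30, 20)))
        a = sample_predictors(table, 5, seed=42)
        b = sample_predictors(table, 5, seed=42)
        np.testing.assert_array_equal(a.traces, b.traces)

    def test_count_too_large(self, rng):
        table = CellTable(positions=rng.uniform(0, 100, (5, 3)), dff=rng.normal(size=(30, 5)))
        with pytest.raises(ValueError):
            sample_predictors(table, 6, seed=0)

    def test_sampling_is_uniform(self, rng):
        table = CellTable(positions=rng.uniform(0, 100, (10, 3)), dff=rng.normal(size=(12, 10)))
        counts = np.zeros(10)
        key = table.dff.sum(axis=0)
        for s in range(10_000):
            ps = sample_predictors(table, 1, seed=s)
            counts[np.argmin(np.abs(key - ps.traces.sum()))] += 1
        assert stats.chisquare(counts).pvalue > 1e-3


class TestSpatialShuffle:
    def test_identity_permutation_possible(self, rng):
        table = CellTable(positions=rng.uniform(0, 100, (6, 3)), dff=rng.normal(size=(20, 6)))
        shuf = spatial_shuffle(table, seed=3)
        # multisets preserved
        np.testing.assert_allclose(
            np.sort(shuf.positions, axis=0), np.sort(table.positions, axis=0)
        )
        np.testing.assert_array_equal(shuf.dff, table.dff)

    def test_breaks_position_trace_association(self, rng):
        table = CellTable(positions=rng.uniform(0, 100, (200, 3)), dff=rng.normal(size=(20, 200)))
        shuf = spatial_shuffle(table, seed=1)
        assert not np.allclose(shuf.positions, table.positions)


class TestRidge:
    def test_solver_matches_normal_equation_oracle(self, rng):
        X = rng.normal(size=(5, 3))
        Y = rng.normal(size=(5, 2))
        alpha = 0.7
        W = _ridge_solve(X.T @ X, X.T @ Y, alpha)
        oracle = np.linalg.inv(X.T @ X + alpha * np.eye(3)) @ X.T @ Y
        np.testing.assert_allclose(W, oracle, atol=1e-10)

    def test_realizable_target_r2_near_one(self, rng):
        T = 600
        split = split_timepoints(T)
        X = rng.normal(size=(T, 10))
        Y = X @ rng.normal(size=(10, 4))
        res = ridge_predict(X, Y, split, RegressionConfig())
        assert res["r2_weighted"] > 0.999

    def test_noise_target_no_spurious_r2(self, rng):
        T = 600
        split = split_timepoints(T)
        X = rng.normal(size=(T, 50))
        Y = rng.normal(size=(T, 200))
        res = ridge_predict(X, Y, split, RegressionConfig())
        assert res["r2_weighted"] <= 0.05

    def test_alpha_never_selected_on_test(self, rng):
        """Corrupting the test-set targets must not change the selected α."""
        T = 600
        split = split_timepoints(T)
        X = rng.normal(size=(T, 10))
        Y = X @ rng.normal(size=(10, 3)) + 0.5 * rng.normal(size=(T, 3))
        a1 = ridge_predict(X, Y, split, RegressionConfig())["alpha"]
        Y2 = Y.copy()
        Y2[split.test] = rng.normal(size=(split.test.size, 3)) * 100
        a2 = ridge_predict(X, Y2, split, RegressionConfig())["alpha"]
        assert a1 == a2

    def test_variance_weighted_average(self):
        assert variance_weighted_r2(np.array([0.5, 0.9]), np.array([1.0, 3.0])) == pytest.approx(0.8)


class TestPredictBrainwide:
    def test_r2_increases_with_predictor_count(self, latent10_population):
        _, table = latent10_population
        cfg = RegressionConfig(n_seeds=2)
        means = [
            predict_brainwide(table, "cells", count=K, config=cfg, n_folds=1).r2_weighted.mean()
            for K in (5, 20, 100)
        ]
        assert means[1] > means[0] - 0.02
        assert means[2] > means[0]

    def test_report_schema(self, latent10_population):
        _, table = latent10_population
        df = predict_brainwide(
            table, "voxels", count=10, voxel_size_um=100.0, config=RegressionConfig(n_seeds=1), n_folds=2
        )
        assert set(df.columns) >= {"predictor_type", "count", "seed", "fold", "r2_weighted"}
        assert len(df) == 2
        assert (df["count"] == 10).all()


class TestPcrDimensionality:
    def test_rank_one_noise_free(self):
        T, N = 600, 40
        t = np.sin(np.linspace(0, 40, T))
        loadings = np.linspace(1, 2, N)
        dff = np.outer(t, loadings)
        table = CellTable(positions=np.random.default_rng(0).uniform(0, 100, (N, 3)), dff=dff)
        dim, curve, r2 = pcr_dimensionality(table, max_components=10, seed=0)
        assert dim == 1
        assert r2 > 0.999

    def test_ten_latent_dims_recovered(self, latent10_population):
        _, table = latent10_population
        dim, curve, r2 = pcr_dimensionality(table, max_components=60, seed=0)
        assert abs(dim - 10) <= 2
        assert r2 > 0.8
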