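"""Normal-score transform, grid construction, and sequential simulation."""

import numpy as np
import pytest

from frapmap.exceptions import NumericalError, ValidationError
from frapmap.sgs import (
    SimulationGrid,
    back_transform,
    build_grid,
    normal_score,
    random_path,
    run_ensemble,
    sgs_realization,
)
from frapmap.variogram import PointSamples, VariogramModel


class TestNormalScore:
    def test_round_trip_identity(self):
        x = np.array([0.3, 1.7, 0.9, 2.4, 1.1])
        scores, ns_map = normal_score(x)
        np.testing.assert_allclose(back_transform(scores, ns_map), x, atol=1e-12)

    def test_scores_have_zero_mean(self):
        rng = np.random.default_rng(1)
        scores, _ = normal_score(rng.lognormal(0, 1, 41))
        assert scores.mean() == pytest.approx(0.0, abs=1e-10)

    def test_median_maps_to_zero_score(self):
        x = np.array([5.0, 1.0, 3.0, 9.0, 7.0])  # odd length; median 5
        scores, _ = normal_score(x)
        assert scores[0] == pytest.approx(0.0, abs=1e-12)

    def test_ties_share_a_score(self):
        scores, _ = normal_score(np.array([1.0, 2.0, 2.0, 3.0]))
        assert scores[1] == scores[2]

    def test_constant_input_rejected(self):
        with pytest.raises(ValidationError):
            normal_score(np.full(5, 3.0))

    def test_tail_extrapolation_clamped_at_floor(self):
        x = np.array([0.1, 0.5, 1.0, 2.0])
        _, ns_map = normal_score(x)
        low = back_transform(np.array([-10.0]), ns_map, floor=0.0)
        assert low[0] >= 0.0

    def test_midpoint_interpolation(self):
        x = np.array([1.0, 2.0, 4.0])
        scores, ns_map = normal_score(x)
        mid = 0.5 * (ns_map.scores[0] + ns_map.scores[1])
        val = back_transform(np.array([mid]), ns_map)[0]
        assert val == pytest.approx(0.5 * (1.0 + 2.0))


class TestGrid:
    def test_full_mask_downsamples_to_all_nodes(self):
        grid = build_grid(np.ones((140, 140), dtype=bool), 0.5, (70, 70))
        assert grid.shape == (70, 70)
        assert grid.n_nodes == 4900

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError):
            build_grid(np.zeros((64, 64), dtype=bool), 0.5)

    def test_disc_mask_matches_block_counting_oracle(self):
        yy, xx = np.mgrid[0:96, 0:96]
        mask = (xx - 48) ** 2 + (yy - 48) ** 2 <= 40**2
        grid = build_grid(mask, 0.5, (24, 24))
        # brute-force 4x4 block counting with the >=50% rule
        count = 0
        for R in range(24):
            for C in range(24):
                block = mask[4 * R: 4 * R + 4, 4 * C: 4 * C + 4]
                if block.mean() >= 0.5:
                    count += 1
        assert grid.n_nodes == count

    def test_node_positions_are_block_centers(self):
        grid = build_grid(np.ones((8, 8), dtype=bool), 1.0, (4, 4))
        # 2x2 blocks of 1-um pixels: first block center at (0.5, 0.5)
        assert tuple(grid.nodes[0]) == (0.5, 0.5)
        assert grid.pitch == (2.0, 2.0)


class TestRandomPath:
    def test_is_a_permutation(self):
        path = random_path(100, seed=3)
        np.testing.assert_array_equal(np.sort(path), np.arange(100))

    def test_reproducible_and_seed_sensitive(self):
        a = random_path(4900, seed=5)
        b = random_path(4900, seed=5)
        c = random_path(4900, seed=6)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)


@pytest.fixture
def ns_setup(small_grid):
    rng = np.random.default_rng(8)
    idx = rng.choice(small_grid.n_nodes, 15, replace=False)
    u = small_grid.nodes[idx]
    z = rng.normal(0, 1, 15)
    return PointSamples(u=u, z=z), VariogramModel(a=15.0, b=0.0, c=1.0)


class TestRealization:
    def test_deterministic_given_seed(self, ns_setup, small_grid):
        pts, model = ns_setup
        a = sgs_realization(pts, model, small_grid, seed=9)
        b = sgs_realization(pts, model, small_grid, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_zero_noise_is_pure_sequential_kriging(self, ns_setup, small_grid):
        pts, model = ns_setup
        a = sgs_realization(pts, model, small_grid, seed=1, noise_scale=0.0)
        b = sgs_realization(pts, model, small_grid, seed=2, noise_scale=0.0,
                            k_neighbors=10**6)
        # with full conditioning the sequential-kriging map is path-independent
        # and equals the global kriging surface
        from frapmap.kriging import krige_map

        est, _ = krige_map(pts, model, small_grid)
        np.testing.assert_allclose(b, est[small_grid.mask], atol=1e-9)
        assert np.all(np.isfinite(a))

    def test_datum_coincident_node_honored_with_zero_nugget(self, small_grid):
        model = VariogramModel(a=15.0, b=0.0, c=1.0)
        u = small_grid.nodes[[3, 40, 100]]
        pts = PointSamples(u=u, z=np.array([-1.0, 0.5, 1.5]))
        vals = sgs_realization(pts, model, small_grid, seed=4)
        np.testing.assert_allclose(vals[[3, 40, 100]], pts.z, atol=1e-8)

    def test_degenerate_variogram_rejected(self, small_grid):
        pts = PointSamples(u=[[1.0, 1.0], [5.0, 5.0], [9.0, 3.0]], z=[0.1, 0.2, 0.3])
        with pytest.raises(NumericalError):
            sgs_realization(pts, VariogramModel(a=1.0, b=0.0, c=0.0), small_grid, seed=0)


class TestEnsemble:
    def test_single_realization_mean_is_itself(self, ns_setup, small_grid):
        pts, model = ns_setup
        ens = run_ensemble(pts, model, small_grid, n_real=1, master_seed=7,
                           normal_score_map=None, value_floor=None)
        np.testing.assert_array_equal(ens.mean_values, ens.realizations[0])
        np.testing.assert_array_equal(ens.sd_values, np.zeros(small_grid.n_nodes))

    def test_zero_spread_at_conditioned_node(self, small_grid):
        model = VariogramModel(a=15.0, b=0.0, c=1.0)
        u = small_grid.nodes[[10, 60, 150]]
        pts = PointSamples(u=u, z=np.array([-0.5, 0.2, 1.0]))
        ens = run_ensemble(pts, model, small_grid, n_real=20, master_seed=2,
                           normal_score_map=None, value_floor=None)
        assert ens.sd_values[[10, 60, 150]] == pytest.approx(0.0, abs=1e-8)

    def test_summary_maps_are_column_statistics(self, ns_setup, small_grid):
        pts, model = ns_setup
        ens = run_ensemble(pts, model, small_grid, n_real=10, master_seed=3,
                           normal_score_map=None, value_floor=None)
        np.testing.assert_allclose(ens.mean_values, ens.realizations.mean(axis=0))
        np.testing.assert_allclose(ens.sd_values, ens.realizations.std(axis=0))

    def test_spread_larger_far_from_data(self, small_grid):
        # nodes far from every measurement should carry more ensemble spread
        model = VariogramModel(a=10.0, b=0.0, c=1.0)
        rng = np.random.default_rng(12)
        centroid = small_grid.nodes.mean(axis=0)
        near = centroid + rng.normal(0, 4, (12, 2))
        pts = PointSamples(u=near, z=rng.normal(0, 1, 12))
        ens = run_ensemble(pts, model, small_grid, n_real=40, master_seed=5,
                           normal_score_map=None, value_floor=None)
        from scipy.spatial.distance import cdist

        dmin = cdist(small_grid.nodes, pts.u).min(axis=1)
        far = dmin > np.quantile(dmin, 0.8)
        close = dmin < np.quantile(dmin, 0.2)
        assert ens.sd_values[far].mean() > ens.sd_values[close].mean()

    def test_histogram_reproduction(self, cell_grid):
        # pooled back-transformed realization values should resemble the
        # data distribution (two-sample KS at alpha=0.01, most seeds)
        from scipy.stats import ks_2samp

        from frapmap.sgs import normal_score
        from frapmap.variogram import fit_exponential, semivariogram_cloud

        rng = np.random.default_rng(21)
        passed = 0
        n_trials = 10
        for trial in range(n_trials):
            idx = rng.choice(cell_grid.n_nodes, 30, replace=False)
            z = rng.lognormal(0, 0.5, 30)
            pts_raw = PointSamples(u=cell_grid.nodes[idx], z=z)
            scores, ns_map = normal_score(z)
            pts = PointSamples(u=pts_raw.u, z=scores)
            model = fit_exponential(semivariogram_cloud(pts))
            ens = run_ensemble(pts, model, cell_grid, n_real=20,
                               master_seed=trial, normal_score_map=ns_map)
            pooled = ens.realizations.ravel()
            sub = rng.choice(pooled, 300, replace=False)
            if ks_2samp(sub, z).pvalue > 0.01:
                passed += 1
        assert passed >= 9
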