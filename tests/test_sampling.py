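"""Ground-truth fields, sampling patterns, error metrics, and sweeps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from frapmap.exceptions import ValidationError
from frapmap.sampling import (
    crescent_mask,
    ellipse_mask,
    equivalent_radius,
    error_metrics,
    gaussian_sampling,
    lattice_sampling,
    make_radial_field,
    make_stepwise_field,
    plateau_onset,
    reconstruct_sgs,
    SweepResult,
    sweep_sigma,
    _inside,
)
from frapmap.sgs import build_grid
from frapmap.synthetic import sample_points_from_field
from frapmap.variogram import PointSamples, VariogramModel
from frapmap.kriging import krige_map


class TestFields:
    def test_radial_field_endpoints(self, cell_grid):
        field = make_radial_field(cell_grid, D_center=0.5, D_edge=2.0)
        d = np.linalg.norm(cell_grid.nodes - cell_grid.nodes.mean(axis=0), axis=1)
        assert field.values[d.argmin()] == pytest.approx(0.5, abs=0.1)
        assert field.values[d.argmax()] == pytest.approx(2.0)

    def test_radial_field_monotone_along_radius(self, cell_grid):
        field = make_radial_field(cell_grid)
        d = np.linalg.norm(cell_grid.nodes - cell_grid.nodes.mean(axis=0), axis=1)
        order = np.argsort(d)
        assert np.all(np.diff(field.values[order]) >= -1e-12)

    def test_stepwise_single_ring_is_constant(self, cell_grid):
        field = make_stepwise_field(cell_grid, levels=[1.5])
        np.testing.assert_array_equal(field.values, 1.5)

    def test_stepwise_values_in_levels(self, cell_grid):
        levels = [0.5, 1.0, 1.5, 2.0]
        field = make_stepwise_field(cell_grid, levels=levels)
        assert set(np.unique(field.values)) <= set(levels)

    def test_stepwise_rings_match_quantile_oracle(self, cell_grid):
        levels = np.array([0.5, 1.0, 2.0])
        field = make_stepwise_field(cell_grid, levels=levels)
        d = np.linalg.norm(cell_grid.nodes - cell_grid.nodes.mean(axis=0), axis=1)
        q1, q2 = np.quantile(d, [1 / 3, 2 / 3])
        expect = np.where(d <= q1, 0.5, np.where(d <= q2, 1.0, 2.0))
        np.testing.assert_array_equal(field.values, expect)

    def test_nonpositive_level_rejected(self, cell_grid):
        with pytest.raises(ValidationError):
            make_stepwise_field(cell_grid, levels=[1.0, -0.5])


class TestEquivalentRadius:
    def test_disc_mask(self):
        yy, xx = np.mgrid[0:200, 0:200]
        mask = (xx - 100) ** 2 + (yy - 100) ** 2 <= 100**2  # radius 10 um at 0.1 um/px
        R = equivalent_radius(mask, pixel_size=0.1)
        assert R == pytest.approx(10.0, abs=0.1)

    def test_area_definition_shape_independent(self):
        mask = np.zeros((200, 400), bool)
        mask[:100, :200] = True  # 100*200 px of 1 um^2 = 20000 um^2
        assert equivalent_radius(mask, 1.0) == pytest.approx(np.sqrt(20000 / np.pi))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError):
            equivalent_radius(np.zeros((10, 10), bool), 1.0)


class TestPatterns:
    def test_gaussian_points_inside_mask(self, cell_grid):
        pat = gaussian_sampling(cell_grid, sigma=10.0, n_points=30, seed=1,
                                min_spacing=2.0)
        assert pat.n_points == 30
        assert _inside(cell_grid, pat.positions).all()

    def test_gaussian_reproducible(self, cell_grid):
        a = gaussian_sampling(cell_grid, sigma=8.0, n_points=20, seed=3, min_spacing=2.0)
        b = gaussian_sampling(cell_grid, sigma=8.0, n_points=20, seed=3, min_spacing=2.0)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_min_spacing_honored(self, cell_grid):
        from scipy.spatial.distance import pdist

        pat = gaussian_sampling(cell_grid, sigma=12.0, n_points=15, seed=2,
                                min_spacing=6.0)
        assert pdist(pat.positions).min() >= 6.0

    def test_narrow_sigma_concentrates_at_centroid(self, cell_grid):
        pat = gaussian_sampling(cell_grid, sigma=0.3, n_points=10, seed=4,
                                min_spacing=0.0)
        centroid = cell_grid.nodes.mean(axis=0)
        mean_dist = np.linalg.norm(pat.positions - centroid, axis=1).mean()
        assert mean_dist < 1.5

    def test_infeasible_packing_reports_achieved_count(self, cell_grid):
        with pytest.raises(ValidationError, match="achieved"):
            gaussian_sampling(cell_grid, sigma=5.0, n_points=200, seed=0,
                              min_spacing=10.0, max_attempts=20000)

    def test_lattice_counts_match_brute_force(self, cell_grid):
        spacing = 7.0
        pat = lattice_sampling(cell_grid, spacing)
        centroid = cell_grid.nodes.mean(axis=0)
        count = 0
        for i in range(-20, 21):
            for j in range(-20, 21):
                p = centroid + np.array([i * spacing, j * spacing])
                if _inside(cell_grid, p[None, :])[0]:
                    count += 1
        assert pat.n_points == count
        assert _inside(cell_grid, pat.positions).all()

    def test_huge_spacing_gives_at_most_one_point(self, cell_grid):
        pat = lattice_sampling(cell_grid, spacing=500.0)
        assert pat.n_points <= 1


class TestErrorMetrics:
    def test_perfect_estimate(self):
        v = np.arange(10, dtype=float) + 1
        m = error_metrics(v, v.copy())
        assert m["mae"] == 0.0 and m["rmse"] == 0.0

    def test_constant_offset(self):
        v = np.ones(8)
        m = error_metrics(v, v + 0.7)
        assert m["mae"] == pytest.approx(0.7)
        assert m["rmse"] == pytest.approx(0.7)

    def test_half_off_by_two(self):
        truth = np.zeros(10)
        est = np.concatenate([np.full(5, 2.0), np.zeros(5)])
        m = error_metrics(truth, est)
        assert m["mae"] == pytest.approx(1.0)
        assert m["rmse"] == pytest.approx(np.sqrt(2.0))

    def test_mismatched_node_sets_rejected(self):
        with pytest.raises(ValidationError):
            error_metrics(np.zeros(5), np.zeros(6))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_mae_never_exceeds_rmse(self, seed):
        rng = np.random.default_rng(seed)
        truth = rng.normal(1, 0.5, 30)
        est = truth + rng.normal(0, 0.3, 30)
        m = error_metrics(truth, est)
        assert m["mae"] <= m["rmse"] + 1e-12


class TestReconstruction:
    def test_ok_with_all_nodes_and_zero_nugget_is_exact(self, small_grid):
        # conditioning on every grid node with no nugget reproduces the field
        field = make_radial_field(small_grid)
        pts = PointSamples(u=small_grid.nodes, z=field.values)
        model = VariogramModel(a=15.0, b=0.0, c=1.0)
        est, _ = krige_map(pts, model, small_grid)
        m = error_metrics(field.values, est[small_grid.mask])
        assert m["mae"] == pytest.approx(0.0, abs=1e-7)

    def test_sgs_reconstruction_beats_global_mean(self, cell_grid):
        field = make_radial_field(cell_grid)
        R = equivalent_radius(cell_grid)
        pat = gaussian_sampling(cell_grid, sigma=0.56 * R, n_points=30, seed=11,
                                min_spacing=2.0)
        pts = sample_points_from_field(field.values, cell_grid, pat.positions)
        est, _ = reconstruct_sgs(pts, cell_grid, n_real=25, master_seed=11)
        mae_sgs = error_metrics(field.values, est)["mae"]
        mae_mean = error_metrics(field.values,
                                 np.full_like(field.values, pts.z.mean()))["mae"]
        assert mae_sgs < mae_mean


class TestSweeps:
    def test_sweep_reproducible_under_master_seed(self, cell_grid):
        field = make_radial_field(cell_grid)
        kw = dict(sigma_over_R_list=[0.3, 0.6], n_points=15, repeats=2,
                  master_seed=9, n_real=5)
        a = sweep_sigma(cell_grid, field, **kw)
        b = sweep_sigma(cell_grid, field, **kw)
        np.testing.assert_array_equal(a.mae_mean, b.mae_mean)
        np.testing.assert_array_equal(a.rmse_mean, b.rmse_mean)

    def test_plateau_onset_rule(self):
        sweep = SweepResult(
            sweep_values=np.array([0.1, 0.3, 0.5, 0.7]),
            mae_mean=np.array([0.5, 0.2, 0.105, 0.1]),
            mae_sd=np.zeros(4), rmse_mean=np.zeros(4), rmse_sd=np.zeros(4),
            n_repeats=1, master_seed=0,
        )
        assert plateau_onset(sweep, tol=0.10) == 0.5

    def test_more_measurement_points_reduce_error(self, cell_grid):
        # both predictors improve on average with denser sampling, and the
        # SGS realization-to-realization spread shrinks
        from frapmap.sampling import sweep_npoints

        field = make_radial_field(cell_grid)
        ok = sweep_npoints(cell_grid, field, n_list=[10, 40], method="ok",
                           repeats=4, master_seed=3, n_real=10)
        sgs = sweep_npoints(cell_grid, field, n_list=[10, 40], method="sgs",
                            repeats=4, master_seed=3, n_real=10)
        assert ok.loc[1, "mae_mean"] < ok.loc[0, "mae_mean"]
        assert sgs.loc[1, "mae_mean"] < sgs.loc[0, "mae_mean"]
        assert sgs.loc[1, "spread_mean"] < sgs.loc[0, "spread_mean"]

    def test_sd_shrinks_with_more_repeats(self, cell_grid):
        # standard error of the mean MAE falls as repeats grow
        field = make_radial_field(cell_grid)
        a = sweep_sigma(cell_grid, field, [0.5], n_points=15, repeats=4,
                        master_seed=1, n_real=5)
        b = sweep_sigma(cell_grid, field, [0.5], n_points=15, repeats=16,
                        master_seed=1, n_real=5)
        se_a = a.mae_sd[0] / np.sqrt(a.n_repeats)
        se_b = b.mae_sd[0] / np.sqrt(b.n_repeats)
        assert se_b < se_a


class TestMasks:
    def test_crescent_is_more_elongated_than_ellipse(self):
        e = build_grid(ellipse_mask(), 0.5, (35, 35))
        c = build_grid(crescent_mask(), 0.5, (35, 35))
        for g in (e, c):
            assert g.n_nodes > 50

        def aspect(grid):
            span = grid.nodes.max(axis=0) - grid.nodes.min(axis=0)
            return span.max() / span.min()

        assert aspect(c) > aspect(e)
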