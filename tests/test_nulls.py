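"""Null ensembles, comparison statistics, attribution, attraction fitting."""

import numpy as np
import pytest

from vesselprox.core import Calibration, CellSet, RegionOfInterest, VesselMask
from vesselprox.nulls import (
    NullEnsemble,
    compare,
    fit_attraction,
    ks_statistic,
    null_all_pixels,
    null_matched_number,
    null_reposition_observed,
)
from vesselprox.proximity import compute_distance_field
from vesselprox.synthetic import place_cells

CAL = Calibration(pixel_size=1.0)


def tiny_map():
    """1×5 grid with the vessel in column 0: pixel distances are {1,2,3,4}."""
    grid = np.zeros((1, 5), dtype=bool)
    grid[0, 0] = True
    return VesselMask(grid=grid, calibration=CAL)


class TestRepositionNull:
    def test_single_extravascular_pixel_forces_placement(self):
        # one extravascular ROI pixel, 3 μm from the vessel: every placement
        # lands there
        grid = np.zeros((1, 4), dtype=bool)
        grid[0, 0] = True
        roi = np.zeros((1, 4), dtype=bool)
        roi[0, [0, 3]] = True
        mask = VesselMask(grid=grid, calibration=CAL)
        cells = CellSet(points=np.array([[0.5, 0.5]] * 4))
        ens = null_reposition_observed(cells, mask, RegionOfInterest(raster=roi),
                                       n_reps=10, seed=1)
        for rep in ens.replicates:
            assert np.all(rep == 3.0)

    def test_same_seed_bitwise_identical(self, dense_scene):
        cells = dense_scene.cells
        a = null_reposition_observed(cells, dense_scene.mask, dense_scene.roi,
                                     n_reps=20, seed=5)
        b = null_reposition_observed(cells, dense_scene.mask, dense_scene.roi,
                                     n_reps=20, seed=5)
        for ra, rb in zip(a.replicates, b.replicates):
            assert ra.tobytes() == rb.tobytes()

    def test_pooled_mean_matches_pixel_population(self, dense_scene, dense_field):
        """Replicate-pooled mean converges to the all-pixel mean (within 3 SE)."""
        ens = null_reposition_observed(
            dense_scene.cells, dense_scene.mask, dense_scene.roi,
            n_reps=200, seed=3,
        )
        pop = dense_field.extravascular_distances()
        se = pop.std() / np.sqrt(ens.pooled().size)
        assert abs(ens.mean() - pop.mean()) < 3 * se

    def test_no_extravascular_pixels_errors(self):
        mask = VesselMask(grid=np.ones((3, 3), dtype=bool), calibration=CAL)
        with pytest.raises(ValueError, match="extravascular"):
            null_reposition_observed(CellSet(points=np.array([[1.0, 1.0]])),
                                     mask, None, n_reps=5, seed=0)


class TestMatchedNumberNull:
    def test_zero_cells_flagged_empty(self, caplog):
        ens = null_matched_number(tiny_map(), None, n_cells=0, n_reps=3, seed=0)
        assert all(r.size == 0 for r in ens.replicates)

    def test_equals_reposition_with_matching_n_and_seed(self, dense_scene):
        cells = dense_scene.cells
        a = null_reposition_observed(cells, dense_scene.mask, dense_scene.roi,
                                     n_reps=10, seed=9)
        b = null_matched_number(dense_scene.mask, dense_scene.roi,
                                n_cells=len(cells), n_reps=10, seed=9)
        for ra, rb in zip(a.replicates, b.replicates):
            assert ra.tobytes() == rb.tobytes()

    def test_large_n_converges_to_pixel_distribution(self, dense_scene, dense_field):
        """Law of large numbers: n=1e5 single replicate within KS < 0.02."""
        ens = null_matched_number(dense_scene.mask, dense_scene.roi,
                                  n_cells=100_000, n_reps=1, seed=2)
        pix = null_all_pixels(dense_field)
        ks = ks_statistic(ens.pooled(), pix.pooled())
        assert ks < 0.02


class TestAllPixelsNull:
    def test_analytic_1x5_grid(self):
        field = compute_distance_field(tiny_map())
        ens = null_all_pixels(field)
        assert sorted(ens.pooled()) == [1.0, 2.0, 3.0, 4.0]
        assert ens.pooled_ecdf(2.0) == 0.5
        assert ens.n_replicates == 1 and ens.seed is None

    def test_degenerate_constant_field(self):
        # vessel column 0 and ROI restricted to column 1: single-valued ECDF
        grid = np.zeros((3, 2), dtype=bool)
        grid[:, 0] = True
        roi = np.zeros((3, 2), dtype=bool)
        roi[:, 1] = True
        mask = VesselMask(grid=grid, calibration=CAL)
        field = compute_distance_field(mask, RegionOfInterest(raster=roi))
        ens = null_all_pixels(field)
        assert np.all(ens.pooled() == 1.0)

    def test_mean_equals_direct_summation(self, dense_field):
        ens = null_all_pixels(dense_field)
        roi = dense_field.roi & (dense_field.values > 0)
        direct = dense_field.values[roi].sum() / roi.sum()
        assert np.isclose(ens.mean(), direct, rtol=0, atol=1e-12)


class TestKsStatistic:
    def test_identical_samples_give_zero(self):
        x = np.array([1.0, 2.0, 2.0, 5.0])
        assert ks_statistic(x, np.sort(x)) == 0.0

    def test_disjoint_support_gives_one(self):
        assert ks_statistic(np.array([10.0, 11.0]), np.array([1.0, 2.0])) == 1.0

    def test_matches_exhaustive_grid_evaluation(self):
        """Agrees with a brute-force sup over a fine evaluation grid."""
        rng = np.random.default_rng(6)
        for _ in range(20):
            a = np.round(rng.exponential(5, size=30), 1)  # force ties
            b = np.round(rng.exponential(4, size=50), 1)
            bs = np.sort(b)
            d = ks_statistic(a, bs)
            grid = np.unique(np.concatenate([a, b]))
            fa = np.searchsorted(np.sort(a), grid, side="right") / a.size
            fb = np.searchsorted(bs, grid, side="right") / b.size
            assert np.isclose(d, np.max(np.abs(fa - fb)), atol=1e-12)


class TestCompare:
    def test_obs_equal_to_null_sample(self, dense_field):
        ens = null_all_pixels(dense_field)
        res = compare(ens.pooled(), ens, n_mc=99, seed=0)
        assert res.ks_statistic == 0.0
        assert res.mc_p_value == 1.0

    def test_disjoint_support_ks_one(self, dense_field):
        ens = null_all_pixels(dense_field)
        obs = np.full(50, dense_field.values.max() + 100.0)
        res = compare(obs, ens, n_mc=99, seed=0)
        assert res.ks_statistic == 1.0
        assert res.mc_p_value == 1.0 / 100.0

    def test_small_n_mc_rejected(self, dense_field):
        ens = null_all_pixels(dense_field)
        with pytest.raises(ValueError, match="n_mc"):
            compare(np.array([1.0]), ens, n_mc=10)

    def test_p_value_floor_is_add_one(self, dense_field):
        ens = null_all_pixels(dense_field)
        res = compare(np.full(30, 1e6), ens, n_mc=49, seed=1)
        assert res.mc_p_value >= 1.0 / 50.0

    def test_null_calibration_nominal_rate(self, dense_scene, dense_field):
        """CSR observations reject at about the nominal 5% level (quick check;
        the full 200-dataset calibration runs in the acceptance suite)."""
        pop = dense_field.extravascular_distances()
        ens = NullEnsemble(model="all_pixels", replicates=[pop], n_cells=pop.size,
                           seed=None)
        rng = np.random.default_rng(77)
        rejections = 0
        n_trials = 60
        for i in range(n_trials):
            obs = pop[rng.integers(0, pop.size, size=100)]
            res = compare(obs, ens, n_mc=199, seed=1000 + i)
            rejections += res.mc_p_value < 0.05
        assert rejections <= 9  # P(X > 9 | Binomial(60, 0.05)) < 1e-3


class TestAttributeShift:
    def test_identical_inputs_verdict_none(self, dense_scene, dense_field):
        from vesselprox.nulls import attribute_shift
        from vesselprox.proximity import cell_distances

        obs = cell_distances(dense_scene.cells, dense_field)
        table = attribute_shift(
            obs, obs, dense_scene.mask, dense_scene.mask,
            dense_scene.roi, dense_scene.roi, n_reps=50, n_mc=99, seed=4,
        )
        morph = table.loc[table.test == "morphology", "statistic"].iloc[0]
        assert morph == 0.0
        assert table.attrs["verdict"] == "none"

    def test_attraction_difference_detected(self, dense_scene, dense_field):
        from vesselprox.nulls import attribute_shift
        from vesselprox.proximity import cell_distances

        attracted = place_cells(dense_scene.mask, dense_scene.roi, 500,
                                alpha=0.8, lam=15.0, seed=21)
        csr = place_cells(dense_scene.mask, dense_scene.roi, 500,
                          alpha=0.0, lam=15.0, seed=22)
        obs_a = cell_distances(attracted, dense_field)
        obs_b = cell_distances(csr, dense_field)
        table = attribute_shift(
            obs_a, obs_b, dense_scene.mask, dense_scene.mask,
            dense_scene.roi, dense_scene.roi, n_reps=200, n_mc=199, seed=8,
        )
        assert table.attrs["factors"] == ["cell-vessel attraction"]
        p_a = table.loc[table.test == "attraction_A", "p_value"].iloc[0]
        p_b = table.loc[table.test == "attraction_B", "p_value"].iloc[0]
        assert p_a < 0.01 < p_b

    def test_morphology_difference_detected(self, dense_scene, sparse_scene,
                                            dense_field, sparse_field):
        from vesselprox.nulls import attribute_shift
        from vesselprox.proximity import cell_distances

        ca = place_cells(dense_scene.mask, dense_scene.roi, 500, 0.0, 15.0, seed=31)
        cb = place_cells(sparse_scene.mask, sparse_scene.roi, 500, 0.0, 15.0, seed=32)
        table = attribute_shift(
            cell_distances(ca, dense_field), cell_distances(cb, sparse_field),
            dense_scene.mask, sparse_scene.mask, dense_scene.roi, sparse_scene.roi,
            n_reps=200, n_mc=199, seed=9,
        )
        assert table.attrs["factors"] == ["vascular morphology"]


class TestAttractionFit:
    def test_csr_sample_fits_near_zero_alpha(self, dense_field):
        """Distances resampled from the pixel distribution itself: small α̂."""
        pix = null_all_pixels(dense_field)
        pop = pix.pooled()
        rng = np.random.default_rng(15)
        alphas = []
        for _ in range(10):
            d = pop[rng.integers(0, pop.size, size=500)]
            alphas.append(fit_attraction(d, pix).alpha)
        assert np.median(alphas) < 0.1

    def test_lambda_recovery_on_resolvable_map(self, sparse_scene, sparse_field):
        """Median λ̂ error < 20% at truth λ=15 μm, n=500 (10-rep spot check;
        the 50-rep version runs in the acceptance suite)."""
        from vesselprox.proximity import cell_distances

        pix = null_all_pixels(sparse_field)
        errs = []
        for r in range(10):
            cells = place_cells(sparse_scene.mask, sparse_scene.roi, 500,
                                alpha=0.8, lam=15.0, seed=4000 + r)
            fit = fit_attraction(cell_distances(cells, sparse_field), pix)
            errs.append(abs(fit.lam - 15.0) / 15.0)
        assert np.median(errs) < 0.2

    def test_degenerate_pixel_distribution_flagged(self):
        pop = np.zeros(50)
        ens = NullEnsemble(model="all_pixels", replicates=[pop], n_cells=50,
                           seed=None)
        with pytest.warns(RuntimeWarning, match="identifiable"):
            fit = fit_attraction(np.zeros(20), ens)
        assert not fit.converged
        assert fit.lam > 0
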