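"""Reconstruction engine: EM correctness, adjointness, FBP, scatter estimate."""

import numpy as np
import pytest

from specres import (BackgroundSpec, CollimatorResponse, GridSpec, MatrixModel,
                     OrbitGeometry, PhantomImage, ReconConfig, SinogramSet,
                     SpectSystemModel, dew_scatter_estimate, fbp,
                     forward_project, loglikelihood, mlem, osem, reconstruct,
                     simulate_energy_windows, apply_poisson, EnergyWindowPair)
from specres.phantom import cylinder_mask
from specres.recon import bit_reversed_order, subset_views
from specres.metrics import fit_gaussian_constant, extract_profile

COLL = CollimatorResponse()


class TestSubsets:
    def test_round_robin_partition(self):
        parts = subset_views(12, 4)
        assert [list(p) for p in parts] == [[0, 4, 8], [1, 5, 9], [2, 6, 10],
                                            [3, 7, 11]]
        with pytest.raises(ValueError):
            subset_views(10, 4)

    def test_bit_reversed_order_is_permutation(self):
        for n in (1, 2, 6, 8, 18):
            order = bit_reversed_order(n)
            assert sorted(order) == list(range(n))
        assert bit_reversed_order(8) == [0, 4, 2, 6, 1, 5, 3, 7]


class TestMlem:
    def test_one_iteration_matches_hand_computed_update(self):
        # independent EM oracle on a dense 2x2 system, evaluated in-line
        A = np.array([[1.0, 0.5], [0.5, 1.0]])
        x_true = np.array([2.0, 3.0])
        y = A @ x_true  # [3.5, 4.0]
        x0 = np.ones(2)
        sens = A.T @ np.ones(2)
        oracle = x0 / sens * (A.T @ (y / (A @ x0)))
        assert oracle == pytest.approx([22 / 9, 23 / 9], abs=1e-15)
        x1 = mlem(y, MatrixModel(A), iterations=1)
        assert np.max(np.abs(x1 - oracle)) < 1e-12

    def test_osem_single_subset_equals_mlem_bitwise(self):
        rng = np.random.default_rng(7)
        A = rng.random((12, 5)) + 0.1
        y = A @ (rng.random(5) * 4)
        cfg = ReconConfig(algorithm="OSEM", iterations=6, subsets=1)
        assert np.array_equal(osem(y, MatrixModel(A), cfg),
                              mlem(y, MatrixModel(A), iterations=6))

    def test_em_count_preservation_under_uniform_sensitivity(self):
        rng = np.random.default_rng(8)
        A = rng.random((10, 6)) + 0.05
        A /= A.sum(axis=0, keepdims=True)  # uniform (unit) sensitivity
        y = A @ (rng.random(6) * 9 + 1)
        totals = []
        mlem(y, MatrixModel(A), iterations=5,
             callback=lambda it, x: totals.append((A @ x).sum()))
        assert np.allclose(totals, y.sum(), rtol=1e-6)

    def test_nonnegativity_and_dead_voxels_stay_zero(self):
        rng = np.random.default_rng(9)
        A = rng.random((8, 4)) + 0.1
        A[:, 2] = 0.0  # voxel invisible to every ray
        y = rng.poisson(A @ np.array([1.0, 3.0, 5.0, 2.0])).astype(float)
        x = osem(y, MatrixModel(A),
                 ReconConfig(algorithm="OSEM", iterations=10, subsets=2))
        assert np.all(x >= 0)
        assert x[2] == 0.0

    def test_loglikelihood_nondecreasing_on_spect_data(self):
        g = GridSpec(32, 7.2)
        geom = OrbitGeometry(n_views=24, n_bins=32, bin_mm=7.2)
        act = np.zeros((32, 32))
        act[10, 14] = 5.0
        act[20, 18] = 3.0
        ph = PhantomImage(act, np.zeros_like(act), g)
        y = forward_project(ph, geom, COLL, attenuate=False)
        model = SpectSystemModel(g, geom, COLL)
        lls = []
        mlem(y, model, iterations=20,
             callback=lambda it, x: lls.append(loglikelihood(x, y, model)))
        assert np.all(np.diff(lls) >= -1e-9 * np.abs(lls[0]))


class TestLoglikelihood:
    def test_saturated_value(self):
        A = np.eye(3)
        y = np.array([2.0, 5.0, 1.0])
        L = loglikelihood(y, y, MatrixModel(A))
        assert L == pytest.approx(np.sum(y * np.log(y) - y), rel=1e-12)

    def test_doubling_identity(self):
        rng = np.random.default_rng(10)
        A = rng.random((6, 3)) + 0.2
        x = rng.random(3) + 0.5
        y = rng.poisson(A @ x * 20).astype(float)
        model = MatrixModel(A)
        dL = loglikelihood(2 * x, y, model) - loglikelihood(x, y, model)
        expected = y.sum() * np.log(2) - (A @ x).sum()
        assert dL == pytest.approx(expected, rel=1e-9)

    def test_empty_sinogram(self):
        assert loglikelihood(np.zeros(2), np.array([]),
                             MatrixModel(np.zeros((0, 2)))) == 0.0

    def test_zero_model_with_observed_counts_is_minus_inf(self):
        A = np.zeros((2, 2))
        assert loglikelihood(np.ones(2), np.array([1.0, 0.0]),
                             MatrixModel(A)) == -np.inf


class TestAdjointness:
    @pytest.mark.parametrize("rr, ac", [(False, False), (True, False),
                                        (False, True), (True, True)])
    def test_projector_backprojector_adjoint(self, rr, ac):
        g = GridSpec(64, 3.6)
        geom = OrbitGeometry(n_views=16, n_bins=64, bin_mm=3.6)
        mu = np.where(cylinder_mask(g, 220.0), 0.015, 0.0) if ac else None
        model = SpectSystemModel(g, geom, COLL if rr else None, mu)
        rng = np.random.default_rng(12)
        for _ in range(5):
            x = rng.random((64, 64))
            y = rng.random((16, 64))
            lhs = np.vdot(model.project(x), y)
            rhs = np.vdot(x, model.backproject(y))
            assert abs(lhs - rhs) / abs(lhs) < 1e-6


class TestResolutionRecovery:
    def test_rr_narrows_point_source_at_equal_updates(self):
        g = GridSpec(64, 3.6)
        geom = OrbitGeometry(n_views=60, n_bins=64, bin_mm=3.6)
        act = np.zeros((64, 64))
        act[32, 43] = 1.0  # ~40 mm off-center
        ph = PhantomImage(act, np.zeros_like(act), g)
        y = forward_project(ph, geom, COLL, attenuate=False)
        cfg = ReconConfig(algorithm="OSEM", iterations=5, subsets=6,
                          ac=False, sc=False)
        center = (g.centers_mm()[43], g.centers_mm()[32])

        def width(vol_values):
            prof = extract_profile(vol_values, g, center, "tangential", 30.0)
            return fit_gaussian_constant(prof).fwhm_mm

        x_rr = osem(y, SpectSystemModel(g, geom, COLL), cfg)
        x_no = osem(y, SpectSystemModel(g, geom, None), cfg)
        assert width(x_rr) < width(x_no)


class TestFbp:
    def _geom(self, n=128, views=180):
        g = GridSpec(n, 230.4 / n)
        return g, OrbitGeometry(n_views=views, n_bins=n, bin_mm=g.voxel_mm)

    def test_zero_sinogram_gives_zero_volume(self):
        g, geom = self._geom(64, 30)
        vol = fbp(SinogramSet(np.zeros((30, 64)), None, geom))
        assert np.all(vol.values == 0)

    def test_linearity(self):
        g, geom = self._geom(64, 30)
        rng = np.random.default_rng(13)
        s1 = rng.random((30, 64))
        s2 = rng.random((30, 64))
        v1 = fbp(SinogramSet(s1, None, geom)).values
        v2 = fbp(SinogramSet(s2, None, geom)).values
        v12 = fbp(SinogramSet(1.5 * s1 + 0.25 * s2, None, geom)).values
        assert np.allclose(v12, 1.5 * v1 + 0.25 * v2, atol=1e-9 * np.abs(v12).max())

    def test_disc_reconstruction_accuracy(self):
        # ramp-filtered reconstruction of an unblurred disc: <5% masked RMSE
        g, geom = self._geom(128, 180)
        act = cylinder_mask(g, 90.0).astype(float)
        ph = PhantomImage(act, np.zeros_like(act), g)
        sino = forward_project(ph, geom, collimator=None, attenuate=False)
        vol = fbp(SinogramSet(sino, None, geom),
                  ReconConfig(algorithm="FBP", fbp_filter="ramp"))
        mask = cylinder_mask(g, 70.0)  # interior, away from the sharp edge
        rmse = np.sqrt(np.mean((vol.values[mask] - act[mask]) ** 2))
        assert rmse / act[mask].mean() < 0.05

    def test_point_source_centroid(self):
        g, geom = self._geom(128, 180)
        act = np.zeros((128, 128))
        ph = PhantomImage(act, np.zeros_like(act), g)
        from specres.phantom import deposit_point
        deposit_point(ph.activity, g, (40.0, 0.0), 1.0)
        sino = forward_project(ph, geom, COLL, attenuate=False)
        vol = fbp(SinogramSet(sino, None, geom))
        peak = np.unravel_index(np.argmax(vol.values), vol.values.shape)
        w = vol.values[peak[0] - 5:peak[0] + 6, peak[1] - 5:peak[1] + 6]
        X, Y = g.meshgrid_mm()
        Xw = X[peak[0] - 5:peak[0] + 6, peak[1] - 5:peak[1] + 6]
        Yw = Y[peak[0] - 5:peak[0] + 6, peak[1] - 5:peak[1] + 6]
        w = np.clip(w, 0, None)
        cx, cy = (Xw * w).sum() / w.sum(), (Yw * w).sum() / w.sum()
        assert abs(cx - 40.0) < 0.5 * g.voxel_mm
        assert abs(cy - 0.0) < 0.5 * g.voxel_mm

    def test_cutoff_above_nyquist_rejected(self):
        g, geom = self._geom(64, 10)
        s = SinogramSet(np.ones((10, 64)), None, geom)
        with pytest.raises(ValueError):
            fbp(s, ReconConfig(algorithm="FBP", fbp_cutoff_cyc_mm=1.0))

    def test_matches_independent_fbp_implementation(self):
        # cross-check against skimage.transform.iradon on an odd grid where
        # the rotation-center conventions coincide
        iradon = pytest.importorskip("skimage.transform").iradon
        n = 65
        g = GridSpec(n, 3.6)
        geom = OrbitGeometry(n_views=90, n_bins=n, bin_mm=3.6)
        X, Y = g.meshgrid_mm()
        img = (np.exp(-((X - 20) ** 2 + (Y + 10) ** 2) / (2 * 8**2))
               + 0.5 * np.exp(-((X + 30) ** 2 + (Y - 25) ** 2) / (2 * 12**2)))
        from specres import RotateProjector
        sino = RotateProjector(g, geom).project(img)
        mine = fbp(SinogramSet(sino, None, geom),
                   ReconConfig(algorithm="FBP", fbp_filter="ramp")).values
        theirs = iradon(sino.T, theta=geom.angles_deg, filter_name="ramp",
                        circle=False, output_size=n)[::-1]
        assert np.abs(mine - theirs).max() < 0.01 * np.abs(mine).max()


class TestDewScatter:
    def test_direct_formula(self):
        cfg = ReconConfig(dew_k=0.5)
        lower = np.full((2, 4), 100.0)
        est = dew_scatter_estimate(lower, cfg, 0.15, 0.15)
        assert np.all(est == 50.0)

    def test_zero_lower_window(self):
        est = dew_scatter_estimate(np.zeros((3, 5)), ReconConfig(), 0.15, 0.15)
        assert np.all(est == 0.0)

    def test_zero_width_rejected(self):
        with pytest.raises(ValueError):
            dew_scatter_estimate(np.ones((1, 2)), ReconConfig(), 0.15, 0.0)

    def test_estimate_tracks_true_scatter_globally(self):
        # default dew_k and window model are mutually calibrated:
        # lower gain 2 and k=0.5 recover the true scatter total
        g = GridSpec(64, 3.6)
        geom = OrbitGeometry(n_views=40, n_bins=64, bin_mm=3.6)
        rng = np.random.default_rng(14)
        primary = rng.random((40, 64)) * 200
        s = simulate_energy_windows(primary, geom, EnergyWindowPair())
        s = apply_poisson(s, 20_000, seed=5)
        est = dew_scatter_estimate(s.lower, ReconConfig(), 0.15, 0.15)
        rel_err = abs(est.sum() - s.truth_scatter.sum()) / s.truth_scatter.sum()
        assert rel_err < 0.20


class TestReconstructDispatch:
    def test_scatter_correction_changes_output(self):
        g = GridSpec(64, 3.6)
        geom = OrbitGeometry(n_views=24, n_bins=64, bin_mm=3.6)
        act = np.zeros((64, 64))
        act[30, 40] = 1.0
        mu = np.where(cylinder_mask(g, 220.0), 0.015, 0.0)
        ph = PhantomImage(act, mu, g)
        primary = forward_project(ph, geom, COLL, attenuate=True)
        s = simulate_energy_windows(primary, geom, EnergyWindowPair())
        with_sc = reconstruct(s, ReconConfig(iterations=2, subsets=6),
                              background=BackgroundSpec.cold())
        no_sc = reconstruct(s, ReconConfig(iterations=2, subsets=6, sc=False),
                            background=BackgroundSpec.cold())
        assert not np.allclose(with_sc.values, no_sc.values)
        assert np.all(with_sc.values >= 0)

    def test_invalid_subset_count_rejected(self):
        g = GridSpec(64, 3.6)
        geom = OrbitGeometry(n_views=10, n_bins=64, bin_mm=3.6)
        s = SinogramSet(np.ones((10, 64)), None, geom)
        with pytest.raises(ValueError):
            reconstruct(s, ReconConfig(iterations=1, subsets=3),
                        background=BackgroundSpec.air())
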