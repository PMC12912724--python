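import numpy as np
import pytest

from phasesync import bold, glm


class TestQuadratureDesign:
    def test_identical_directions_flagged_rank_deficient(self, directions):
        same = np.full_like(np.asarray(directions, float), 45.0)
        design = bold.make_event_design(same, seed=0)
        with pytest.raises(ValueError, match="rank"):
            glm.build_quadrature_design(design.session(1), 6)

    def test_angle_wrap_equivalence(self, directions):
        d1 = bold.make_event_design(directions, seed=0)
        d2 = bold.make_event_design(np.asarray(directions) + 360.0, seed=0)
        X1 = glm.build_quadrature_design(d1.session(1), 6)
        X2 = glm.build_quadrature_design(d2.session(1), 6)
        assert np.allclose(X1.matrix, X2.matrix)

    def test_fold_symmetry(self, directions):
        d1 = bold.make_event_design(directions, seed=0)
        d2 = bold.make_event_design((np.asarray(directions) + 60.0) % 360.0, seed=0)
        X1 = glm.build_quadrature_design(d1.session(1), 6)
        X2 = glm.build_quadrature_design(d2.session(1), 6)
        assert np.allclose(X1.matrix, X2.matrix, atol=1e-10)


class TestOrientationEstimation:
    @pytest.mark.parametrize(
        "bs,bc,k,expected",
        [(0.0, 1.0, 6, 0.0), (1.0, 0.0, 6, 15.0), (-1.0, 0.0, 6, 45.0),
         (0.0, 1.0, 3, 0.0), (1.0, 0.0, 3, 30.0)],
    )
    def test_from_betas(self, bs, bc, k, expected):
        fit = glm.QuadratureFit(beta_sine=bs, beta_cosine=bc, fold=k)
        assert glm.orientation_from_betas(fit).phi == pytest.approx(expected)

    def test_zero_vector_rejected(self):
        fit = glm.QuadratureFit(beta_sine=0.0, beta_cosine=0.0, fold=6)
        with pytest.raises(ValueError, match="undefined"):
            glm.orientation_from_betas(fit)

    def test_brute_force_agreement(self):
        """atan2 estimate maximizes the fit of cos(k(theta-phi)) to the tuning curve."""
        rng = np.random.default_rng(0)
        th = np.radians(np.arange(0, 360, 1.0))
        for _ in range(10):
            bs, bc = rng.normal(size=2)
            k = int(rng.integers(3, 8))
            fit = glm.QuadratureFit(beta_sine=bs, beta_cosine=bc, fold=k)
            curve = glm.reconstruct_tuning(fit, np.degrees(th))
            grid = np.arange(0, 360.0 / k, 0.01)
            scores = [curve @ np.cos(k * (th - np.radians(p))) for p in grid]
            brute = grid[int(np.argmax(scores))]
            est = glm.orientation_from_betas(fit).phi
            assert abs((est - brute + 180 / k) % (360 / k) - 180 / k) < 0.02

    @pytest.mark.parametrize("k", [3, 4, 5, 6, 7])
    def test_noiseless_roundtrip_all_folds(self, event_design, k):
        phi = 23.0 % (360.0 / k)
        truth = bold.GroundTruth(fold=k, phi=phi, amplitude=1.0, noise_sd=0.0)
        series = bold.simulate_voxel(event_design, truth, seed=0)
        X = glm.build_quadrature_design(event_design.session(1), k, n_scans=series.shape[1])
        est = glm.orientation_from_betas(glm.fit_quadrature(series[0], X))
        assert est.phi == pytest.approx(phi, abs=1e-6)

    def test_quadrature_phase_relation(self, event_design):
        # phi* = 15 deg at fold 6 puts the beta vector at 90 deg
        truth = bold.GroundTruth(fold=6, phi=15.0, amplitude=1.0, noise_sd=0.0)
        series = bold.simulate_voxel(event_design, truth, seed=0)
        X = glm.build_quadrature_design(event_design.session(1), 6, n_scans=series.shape[1])
        fit = glm.fit_quadrature(series[0], X)
        assert np.degrees(np.arctan2(fit.beta_sine, fit.beta_cosine)) == pytest.approx(
            90.0, abs=1e-6
        )

    def test_equivariance_under_rotation(self, directions):
        """Rotating all directions by delta rotates the estimate by delta mod 360/k."""
        delta = 17.5
        d1 = bold.make_event_design(directions, seed=2)
        rot = (np.asarray(directions) + delta) % 360.0
        d2 = bold.make_event_design(rot, seed=2)
        truth = bold.GroundTruth(fold=6, phi=10.0, amplitude=1.0, noise_sd=0.0)
        s1 = bold.simulate_voxel(d1, truth, seed=0)
        # same voxel signal as a function of original directions, labels rotated:
        # equivalent to planting phi + delta
        truth2 = bold.GroundTruth(fold=6, phi=(10.0 + delta) % 60.0, amplitude=1.0, noise_sd=0.0)
        s2 = bold.simulate_voxel(d2, truth2, seed=0)
        X1 = glm.build_quadrature_design(d1.session(1), 6, n_scans=s1.shape[1])
        X2 = glm.build_quadrature_design(d2.session(1), 6, n_scans=s2.shape[1])
        p1 = glm.orientation_from_betas(glm.fit_quadrature(s1[0], X1)).phi
        p2 = glm.orientation_from_betas(glm.fit_quadrature(s2[0], X2)).phi
        assert (p2 - p1) % 60.0 == pytest.approx(delta % 60.0, abs=1e-6)


class TestMeanOrientation:
    def test_trivial_mean(self):
        ests = [glm.OrientationEstimate(phi=10.0, fold=6)] * 4
        assert glm.mean_grid_orientation(ests).phi == pytest.approx(10.0)

    def test_wrap_aware_mean(self):
        ests = [
            glm.OrientationEstimate(phi=1.0, fold=6),
            glm.OrientationEstimate(phi=59.0, fold=6),
        ]
        assert glm.mean_grid_orientation(ests).phi == pytest.approx(0.0, abs=1e-9)

    def test_antipodal_pair_flagged(self):
        ests = [
            glm.OrientationEstimate(phi=0.0, fold=6),
            glm.OrientationEstimate(phi=30.0, fold=6),
        ]
        with pytest.warns(UserWarning, match="degenerate"):
            out = glm.mean_grid_orientation(ests)
        assert out.low_confidence

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            glm.mean_grid_orientation([])


class TestCrossValidatedAlignment:
    def test_noiseless_recovers_amplitude(self, event_design):
        truth = bold.GroundTruth(fold=6, phi=15.0, amplitude=0.8, noise_sd=0.0)
        series = bold.simulate_voxel(event_design, truth, seed=0)
        assert glm.crossval_alignment(series, event_design, 6) == pytest.approx(0.8, abs=1e-9)

    def test_control_fold_orthogonal(self, event_design):
        truth = bold.GroundTruth(fold=6, phi=15.0, amplitude=1.0, noise_sd=0.0)
        series = bold.simulate_voxel(event_design, truth, seed=0)
        b6 = glm.crossval_alignment(series, event_design, 6)
        for k in (3, 4, 5, 7):
            bk = glm.crossval_alignment(series, event_design, k)
            assert abs(bk) < 0.15 * b6

    def test_zero_amplitude_gives_zero(self, event_design):
        truth = bold.GroundTruth(fold=6, phi=15.0, amplitude=0.0, noise_sd=0.0)
        series = bold.simulate_voxel(event_design, truth, seed=0)
        # without modulation the held-out aligned beta vanishes
        assert abs(glm.crossval_alignment(series, event_design, 6)) < 1e-8

    def test_control_fold_selectivity_across_seeds(self, event_design):
        """Held-out alignment at the planted fold beats every control fold at realistic SNR."""
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            truth = bold.GroundTruth(fold=6, phi=15.0, amplitude=1.0, noise_sd=2.0)
            series = bold.simulate_voxel(event_design, truth, seed=seed)
            b6 = glm.crossval_alignment(series, event_design, 6)
            if all(
                b6 > glm.crossval_alignment(series, event_design, k) for k in (3, 4, 5, 7)
            ):
                wins += 1
        assert wins >= int(0.95 * n_seeds)

    def test_single_session_rejected(self, event_design, noiseless_voxel):
        _, series = noiseless_voxel
        single = event_design.session(1)
        with pytest.raises(ValueError):
            glm.crossval_alignment(series[:1], single, 6)


class TestDirectionBins:
    def test_noiseless_threefold_tuning_traced(self, event_design):
        truth = bold.GroundTruth(fold=3, phi=40.0, amplitude=1.0, baseline=1.0, noise_sd=0.0)
        series = bold.simulate_voxel(event_design, truth, seed=0)
        bins = glm.fit_direction_bins(series[None, :, :], event_design)
        pred = truth.baseline + np.cos(3 * np.radians(bins.bin_centers - truth.phi))
        assert np.corrcoef(bins.betas, pred)[0, 1] > 0.99

    def test_half_open_bin_rule(self):
        # trials at 5 and 10 deg land in bins 0 and 10 respectively
        dirs = np.concatenate([np.full(144, 5.0), np.full(144, 10.0)])
        design = bold.make_event_design(dirs, seed=0)
        truth = bold.GroundTruth(fold=1, phi=0.0, amplitude=1.0, noise_sd=0.0)
        series = bold.simulate_voxel(design, truth, seed=0)
        with pytest.warns(UserWarning, match="empty"):
            bins = glm.fit_direction_bins(series[None, :, :], design)
        occupied = np.flatnonzero(~np.isnan(bins.betas))
        assert occupied.tolist() == [0, 1]


class TestTuningReconstruction:
    def test_sixfold_maxima(self):
        fit = glm.QuadratureFit(beta_sine=0.0, beta_cosine=1.0, fold=6)
        grid = np.arange(0, 360, 0.5)
        curve = glm.reconstruct_tuning(fit, grid)
        peaks = grid[curve >= curve.max() - 1e-12]
        assert np.allclose(peaks, np.arange(0, 360, 60))

    def test_amplitude_identity(self):
        fit = glm.QuadratureFit(beta_sine=0.6, beta_cosine=-0.8, fold=4)
        curve = glm.reconstruct_tuning(fit, np.arange(0, 360, 0.1))
        assert curve.max() == pytest.approx(np.hypot(0.6, 0.8), abs=1e-4)

    def test_peak_at_estimated_orientation(self):
        fit = glm.QuadratureFit(beta_sine=0.5, beta_cosine=0.5, fold=6)
        phi = glm.orientation_from_betas(fit).phi
        val = glm.reconstruct_tuning(fit, np.array([phi]))[0]
        assert val == pytest.approx(fit.amplitude, abs=1e-9)
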