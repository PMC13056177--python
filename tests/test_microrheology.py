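"""MSD computation, GSER conversion and eta* extraction."""

import math

import numpy as np
import pytest

import mucotrack as mt


def brute_force_msd(frames, xs, ys, frame_rate):
    """All-pairs oracle: average squared displacement per integer lag."""
    acc: dict[int, list[float]] = {}
    for i in range(len(frames)):
        for j in range(i + 1, len(frames)):
            lag = frames[j] - frames[i]
            acc.setdefault(lag, []).append(
                (xs[j] - xs[i]) ** 2 + (ys[j] - ys[i]) ** 2
            )
    lags = sorted(acc)
    return (
        np.array([l / frame_rate for l in lags]),
        np.array([np.mean(acc[l]) for l in lags]),
        np.array([len(acc[l]) for l in lags]),
    )


def _track(frames, xs, ys, fps=1.0):
    return mt.Trajectory(0, frames, xs, ys, fps, units="um")


class TestComputeMSD:
    def test_three_point_example(self):
        curve = mt.compute_msd(_track([0, 1, 2], [0.0, 1.0, 1.0], [0.0, 0.0, 1.0]))
        np.testing.assert_allclose(curve.lags, [1.0, 2.0])
        np.testing.assert_allclose(curve.msd, [1.0, 2.0])
        np.testing.assert_array_equal(curve.n_obs, [2, 1])

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_on_short_tracks(self, seed):
        """Oracle equivalence on random tracks of <= 5 points, with gaps."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 6))
        frames = np.sort(rng.choice(np.arange(8), size=n, replace=False))
        xs = rng.normal(size=n)
        ys = rng.normal(size=n)
        curve = mt.compute_msd(_track(frames, xs, ys, fps=2.0))
        lags, msd, n_obs = brute_force_msd(frames, xs, ys, 2.0)
        np.testing.assert_allclose(curve.lags, lags)
        np.testing.assert_allclose(curve.msd, msd)
        np.testing.assert_array_equal(curve.n_obs, n_obs)

    def test_ballistic_track_is_quadratic(self):
        v, fps = 3.0, 10.0
        frames = np.arange(30)
        curve = mt.compute_msd(_track(frames, v * frames / fps, 0 * frames, fps))
        np.testing.assert_allclose(curve.msd, v**2 * curve.lags**2, rtol=1e-12)

    def test_stationary_track_is_zero(self):
        curve = mt.compute_msd(_track([0, 1, 2, 3], [2.0] * 4, [5.0] * 4))
        np.testing.assert_allclose(curve.msd, 0.0)

    def test_pixel_track_requires_calibration(self):
        track = mt.Trajectory(0, [0, 1], [0.0, 1.0], [0.0, 0.0], 1.0, units="px")
        with pytest.raises(ValueError):
            mt.compute_msd(track)
        curve = mt.compute_msd(track, pixel_size=0.5)
        np.testing.assert_allclose(curve.msd, [0.25])


class TestEnsembleMSD:
    def test_identical_curves_pass_through(self):
        c = mt.compute_msd(_track([0, 1, 2], [0.0, 1.0, 1.0], [0.0, 0.0, 1.0]))
        ens = mt.ensemble_msd([c, c, c])
        np.testing.assert_allclose(ens.msd, c.msd)
        np.testing.assert_array_equal(ens.n_obs, 3 * c.n_obs)

    def test_weighted_mean(self):
        a = mt.MSDCurve([1.0], [1.0], [10])
        b = mt.MSDCurve([1.0], [3.0], [30])
        ens = mt.ensemble_msd([a, b])
        assert ens.msd[0] == pytest.approx(2.5)
        assert ens.n_obs[0] == 40

    def test_single_curve_identity(self):
        c = mt.MSDCurve([0.5, 1.0], [1.0, 2.0], [4, 3])
        ens = mt.ensemble_msd([c])
        np.testing.assert_allclose(ens.msd, c.msd)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mt.ensemble_msd([])


class TestGSER:
    def test_newtonian_identity(self):
        """MSD = 4 D tau must return alpha = 1, G' = 0 and eta* = eta exactly."""
        eta = 5e-3
        params = mt.RheoParams()
        d = mt.stokes_einstein_D(params, eta)
        lags = np.arange(1, 60) / 30.0
        curve = mt.MSDCurve(lags, 4.0 * d * lags, np.full(len(lags), 100))
        spec = mt.gser_spectrum(curve, params)
        np.testing.assert_allclose(spec.alpha, 1.0, atol=1e-9)
        np.testing.assert_allclose(spec.eta_star, eta, rtol=1e-9)
        np.testing.assert_allclose(spec.g_storage, 0.0, atol=1e-12)
        np.testing.assert_allclose(spec.g_loss, eta * spec.omega, rtol=1e-9)

    def test_elastic_plateau(self):
        """Constant MSD: alpha = 0, G'' = 0, G' = 2 k_B T / (3 pi a delta^2)."""
        delta2 = 1e-4  # um^2
        params = mt.RheoParams()
        lags = np.arange(1, 30) / 30.0
        curve = mt.MSDCurve(lags, np.full(len(lags), delta2), np.full(len(lags), 50))
        spec = mt.gser_spectrum(curve, params)
        expected = (
            2.0 * params.boltzmann_constant * params.temperature
            / (3.0 * math.pi * params.bead_radius * delta2 * 1e-12)
        )
        np.testing.assert_allclose(spec.alpha, 0.0, atol=1e-9)
        np.testing.assert_allclose(spec.g_loss, 0.0, atol=1e-12)
        np.testing.assert_allclose(spec.g_storage, expected, rtol=1e-9)

    def test_superdiffusive_slope_clipped_to_one(self):
        lags = np.arange(1, 30) / 30.0
        curve = mt.MSDCurve(lags, 0.1 * lags**1.4, np.full(len(lags), 50))
        spec = mt.gser_spectrum(curve, mt.RheoParams())
        np.testing.assert_allclose(spec.alpha, 1.0, atol=1e-9)

    def test_modulus_magnitude_consistency(self):
        rng = np.random.default_rng(3)
        lags = np.arange(1, 40) / 30.0
        msd = 0.01 * lags**0.7 * np.exp(rng.normal(0, 0.02, len(lags)))
        spec = mt.gser_spectrum(mt.MSDCurve(lags, msd, np.full(len(lags), 10)),
                                mt.RheoParams())
        np.testing.assert_allclose(
            spec.g_abs**2, spec.g_storage**2 + spec.g_loss**2, rtol=1e-9
        )

    def test_all_nonpositive_msd_rejected(self):
        curve = mt.MSDCurve([1.0, 2.0], [0.0, 0.0], [5, 5])
        with pytest.raises(ValueError):
            mt.gser_spectrum(curve, mt.RheoParams())


class TestEtaStarAt:
    def _spec(self, omega, eta_star):
        omega = np.asarray(omega, dtype=float)
        eta_star = np.asarray(eta_star, dtype=float)
        g = eta_star * omega
        return mt.ViscoelasticSpectrum(
            omega=omega, alpha=np.ones_like(omega), g_abs=g,
            g_storage=np.zeros_like(g), g_loss=g, eta_star=eta_star,
        )

    def test_loglog_interpolation(self):
        spec = self._spec([1.0, 100.0], [1e-2, 1e-3])
        assert mt.eta_star_at(spec, 10.0) == pytest.approx(10**-2.5, rel=1e-9)

    def test_newtonian_spectrum_flat(self):
        spec = self._spec([0.5, 1.0, 2.0, 4.0], [3e-3] * 4)
        assert mt.eta_star_at(spec, 1.3) == pytest.approx(3e-3, rel=1e-9)

    def test_out_of_range_rejected(self):
        spec = self._spec([1.0, 10.0], [1e-2, 1e-3])
        with pytest.raises(ValueError, match="outside"):
            mt.eta_star_at(spec, 0.1)


class TestEndToEnd:
    @pytest.mark.parametrize("eta", [1e-3, 1e-2, 1e-1])
    def test_newtonian_recovery_within_15_percent(self, eta):
        cfg = mt.BeadSimConfig(
            viscosity=eta, n_particles=100, localization_noise_sd=0.0, seed=17
        )
        tracks, _ = mt.simulate_brownian_tracks(cfg)
        recovered, n = mt.bead_tracks_to_eta_star(tracks, cfg.rheo)
        assert n == 100
        assert recovered == pytest.approx(eta, rel=0.15)

    def test_pixel_size_consistency(self):
        """eta* is identical whether tracks arrive in um or in px + calibration."""
        cfg = mt.BeadSimConfig(viscosity=1e-3, n_particles=20, duration=3.0, seed=4)
        tracks, _ = mt.simulate_brownian_tracks(cfg)
        px = 0.2
        tracks_px = [
            mt.Trajectory(t.particle_id, t.frames, t.x / px, t.y / px,
                          t.frame_rate, units="px")
            for t in tracks
        ]
        eta_um, _ = mt.bead_tracks_to_eta_star(tracks, cfg.rheo)
        eta_px, _ = mt.bead_tracks_to_eta_star(tracks_px, cfg.rheo, pixel_size=px)
        assert eta_px == pytest.approx(eta_um, rel=1e-12)

    def test_drift_correction_restores_eta(self):
        cfg = mt.BeadSimConfig(
            viscosity=1e-2, n_particles=50, drift_velocity=(2.0, -1.5),
            localization_noise_sd=0.0, seed=8,
        )
        tracks, _ = mt.simulate_brownian_tracks(cfg)
        eta_corr, _ = mt.bead_tracks_to_eta_star(tracks, cfg.rheo, drift_correction=True)
        eta_raw, _ = mt.bead_tracks_to_eta_star(tracks, cfg.rheo, drift_correction=False)
        assert eta_corr == pytest.approx(1e-2, rel=0.15)
        assert abs(math.log10(eta_raw / 1e-2)) > abs(math.log10(eta_corr / 1e-2))
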