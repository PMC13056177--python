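"""Simulator module: diffusion physics, swimmer scaling, rendering, cohorts."""

import dataclasses
import math

import numpy as np
import pytest

import mucotrack as mt


class TestStokesEinstein:
    def test_reference_value(self):
        # hand evaluation: k_B T / (6 pi eta a) for water-like buffer
        d = mt.stokes_einstein_D(mt.RheoParams(temperature=293.15), 1e-3)
        assert d == pytest.approx(0.4294, rel=1e-3)

    def test_inverse_proportional_to_viscosity(self):
        p = mt.RheoParams()
        assert mt.stokes_einstein_D(p, 2e-3) == pytest.approx(
            mt.stokes_einstein_D(p, 1e-3) / 2.0, rel=1e-12
        )

    def test_vanishes_with_temperature(self):
        d = mt.stokes_einstein_D(mt.RheoParams(temperature=1e-9), 1e-3)
        assert 0 < d < 1e-9

    @pytest.mark.parametrize(
        "kwargs",
        [dict(temperature=-1.0), dict(bead_radius=0.0), dict(bead_radius=-1e-6)],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            mt.RheoParams(**kwargs)

    def test_nonpositive_viscosity_rejected(self):
        with pytest.raises(ValueError):
            mt.stokes_einstein_D(mt.RheoParams(), 0.0)


class TestBrownianTracks:
    def test_ensemble_msd_slope_matches_4D(self):
        """Independent linear-fit oracle on the raw positions: slope ~ 4D."""
        cfg = mt.BeadSimConfig(
            viscosity=1e-3, n_particles=500, localization_noise_sd=0.0, seed=11
        )
        _, truth = mt.simulate_brownian_tracks(cfg)
        pos = truth.positions  # (n, t, 2)
        dt = 1.0 / cfg.frame_rate
        lags = np.arange(1, int(1.0 / dt) + 1)
        msd = np.array([
            np.mean(np.sum((pos[:, L:, :] - pos[:, :-L, :]) ** 2, axis=-1))
            for L in lags
        ])
        slope = np.polyfit(lags * dt, msd, 1)[0]
        expected = 4.0 * cfg.diffusion_coefficient
        assert slope == pytest.approx(expected, rel=0.05)

    def test_localization_noise_adds_msd_intercept(self):
        sigma = 0.05
        base = mt.BeadSimConfig(
            viscosity=1e-3, n_particles=300, duration=2.0,
            localization_noise_sd=0.0, seed=5,
        )
        noisy = dataclasses.replace(base, localization_noise_sd=sigma)
        clean_tracks, _ = mt.simulate_brownian_tracks(base)
        noisy_tracks, _ = mt.simulate_brownian_tracks(noisy)
        m_clean = mt.ensemble_msd([mt.compute_msd(t) for t in clean_tracks])
        m_noisy = mt.ensemble_msd([mt.compute_msd(t) for t in noisy_tracks])
        offset = np.mean(m_noisy.msd[:5] - m_clean.msd[:5])
        assert offset == pytest.approx(4.0 * sigma**2, rel=0.15)

    def test_huge_viscosity_freezes_particles(self):
        cfg = mt.BeadSimConfig(
            viscosity=1e30, n_particles=3, duration=1.0,
            localization_noise_sd=0.0, seed=0,
        )
        tracks, _ = mt.simulate_brownian_tracks(cfg)
        for t in tracks:
            assert np.allclose(t.x, t.x[0], atol=1e-9)
            assert np.allclose(t.y, t.y[0], atol=1e-9)

    def test_seed_determinism_and_variation(self):
        cfg = mt.BeadSimConfig(viscosity=1e-3, n_particles=5, duration=1.0, seed=3)
        a, _ = mt.simulate_brownian_tracks(cfg)
        b, _ = mt.simulate_brownian_tracks(cfg)
        c, _ = mt.simulate_brownian_tracks(dataclasses.replace(cfg, seed=4))
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.x, tb.x)
            np.testing.assert_array_equal(ta.y, tb.y)
        assert not np.array_equal(a[0].x, c[0].x)

    def test_drift_adds_linear_motion(self):
        cfg = mt.BeadSimConfig(
            viscosity=1e30, n_particles=1, duration=1.0, frame_rate=10.0,
            localization_noise_sd=0.0, drift_velocity=(1.0, -2.0), seed=0,
        )
        tracks, _ = mt.simulate_brownian_tracks(cfg)
        times = tracks[0].frames / cfg.frame_rate
        np.testing.assert_allclose(tracks[0].x, 1.0 * times, atol=1e-9)
        np.testing.assert_allclose(tracks[0].y, -2.0 * times, atol=1e-9)


class TestSwimmerTracks:
    def test_straight_swimmer_speed_is_exact(self):
        cfg = mt.SwimmerSimConfig(
            base_speed=37.0, wobble_amplitude=0.0, speed_dispersion=0.0,
            heading_persistence=math.inf, n_sperm=3, seed=1,
        )
        tracks, truth = mt.simulate_swimmer_tracks(cfg)
        for t, v in zip(tracks, truth.speeds):
            assert v == pytest.approx(37.0)
            net = math.hypot(t.x[-1] - t.x[0], t.y[-1] - t.y[0])
            assert net / t.duration == pytest.approx(v, rel=1e-12)

    def test_concentration_power_law_halves_speed(self):
        # beta = 0.5: quadrupling c halves the median speed
        kw = dict(speed_dispersion=0.0, n_sperm=4, seed=2)
        full = mt.SwimmerSimConfig(relative_concentration=1.0, **kw)
        quarter = mt.SwimmerSimConfig(relative_concentration=0.25, **kw)
        _, truth_full = mt.simulate_swimmer_tracks(full)
        _, truth_quarter = mt.simulate_swimmer_tracks(quarter)
        ratio = np.median(truth_full.speeds) / np.median(truth_quarter.speeds)
        assert ratio == pytest.approx(0.5, rel=1e-12)

    def test_seed_determinism(self):
        cfg = mt.SwimmerSimConfig(n_sperm=4, seed=9)
        a, _ = mt.simulate_swimmer_tracks(cfg)
        b, _ = mt.simulate_swimmer_tracks(cfg)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.x, tb.x)
            np.testing.assert_array_equal(ta.y, tb.y)

    def test_invalid_concentration_rejected(self):
        with pytest.raises(ValueError):
            mt.SwimmerSimConfig(relative_concentration=0.0)
        with pytest.raises(ValueError):
            mt.SwimmerSimConfig(relative_concentration=1.5)


class TestRenderStack:
    def test_argmax_at_integer_center(self):
        track = mt.Trajectory(0, [0, 1], [20.0, 20.0], [30.0, 30.0], 1.0, units="um")
        render = mt.RenderConfig(image_size=(64, 64), pixel_size=1.0, noise_model="none")
        stack = mt.render_stack([track], render, frame_rate=1.0)
        y, x = np.unravel_index(np.argmax(stack.frames[0]), stack.frames[0].shape)
        assert (x, y) == (20, 30)

    def test_integrated_intensity_matches_spot_mass(self):
        # summation oracle: one Gaussian spot integrates to 2 pi sigma^2 * peak
        tracks = [
            mt.Trajectory(i, [0, 1], [x, x], [y, y], 1.0, units="um")
            for i, (x, y) in enumerate([(16.0, 16.0), (48.0, 16.0), (32.0, 48.0)])
        ]
        render = mt.RenderConfig(
            image_size=(64, 64), pixel_size=1.0, psf_sigma=2.0,
            spot_intensity=150.0, background=10.0, noise_model="none",
        )
        stack = mt.render_stack(tracks, render, frame_rate=1.0)
        total = stack.frames[0].astype(float).sum() - 10.0 * 64 * 64
        expected = 3 * 2.0 * math.pi * render.psf_sigma**2 * render.spot_intensity
        assert total == pytest.approx(expected, rel=0.05)

    def test_empty_track_list_gives_pure_background(self):
        render = mt.RenderConfig(background=7.0, noise_model="none")
        stack = mt.render_stack([], render, frame_rate=1.0)
        assert np.all(stack.frames == 7)

    def test_out_of_frame_particle_is_clipped(self):
        track = mt.Trajectory(0, [0, 1], [500.0, 500.0], [500.0, 500.0], 1.0, units="um")
        render = mt.RenderConfig(image_size=(64, 64), pixel_size=1.0, noise_model="none")
        stack = mt.render_stack([track], render, frame_rate=1.0)
        assert np.all(stack.frames == int(render.background))


class TestDilutionSeries:
    def test_point_count(self):
        points = mt.simulate_dilution_series(
            6, (1, 2, 4, 8, 16, 32, 64, 128), seed=0,
            bead_cfg_template=mt.BeadSimConfig(viscosity=1e-3, n_particles=2, duration=0.5),
            swimmer_cfg_template=mt.SwimmerSimConfig(n_sperm=2, duration=0.5),
        )
        assert len(points) == 48
        assert len({(p.animal, p.dilution) for p in points}) == 48
        assert all(len(p.bead_tracks) == 2 and len(p.sperm_tracks) == 3 for p in points)

    def test_zero_noise_lies_exactly_on_power_laws(self):
        eta_buffer, eta_neat, exponent = 1e-3, 0.1, 3.0
        points = mt.simulate_dilution_series(
            1, (1, 2, 4, 8), seed=0,
            rheology_scaling_exponent=exponent,
            eta_buffer=eta_buffer, eta_neat=eta_neat, animal_sd_log10=0.0,
            bead_cfg_template=mt.BeadSimConfig(viscosity=1e-3, n_particles=2, duration=0.5),
            swimmer_cfg_template=mt.SwimmerSimConfig(
                base_speed=10.0, speed_dispersion=0.0, n_sperm=2, duration=0.5
            ),
        )
        for p in points:
            c = 1.0 / p.dilution
            assert p.true_viscosity == pytest.approx(
                eta_buffer + (eta_neat - eta_buffer) * c**exponent, rel=1e-12
            )
            assert p.true_median_speed == pytest.approx(10.0 * c**-0.5, rel=1e-12)
            for truth in p.sperm_truths:
                np.testing.assert_allclose(truth.speeds, p.true_median_speed)

    def test_expected_viscosity_monotone_in_dilution(self):
        points = mt.simulate_dilution_series(
            1, (1, 2, 4, 8, 16, 32, 64, 128), seed=1,
            bead_cfg_template=mt.BeadSimConfig(viscosity=1e-3, n_particles=2, duration=0.5),
            swimmer_cfg_template=mt.SwimmerSimConfig(n_sperm=2, duration=0.5),
        )
        etas = [p.true_viscosity for p in sorted(points, key=lambda p: p.dilution)]
        assert all(b <= a for a, b in zip(etas, etas[1:]))

    def test_empty_dilution_list_rejected(self):
        with pytest.raises(ValueError):
            mt.simulate_dilution_series(1, (), seed=0)

    def test_seed_replay(self):
        kw = dict(
            bead_cfg_template=mt.BeadSimConfig(viscosity=1e-3, n_particles=2, duration=0.5),
            swimmer_cfg_template=mt.SwimmerSimConfig(n_sperm=2, duration=0.5),
        )
        a = mt.simulate_dilution_series(1, (1, 4), seed=5, **kw)
        b = mt.simulate_dilution_series(1, (1, 4), seed=5, **kw)
        np.testing.assert_array_equal(
            a[0].bead_tracks[0][0].x, b[0].bead_tracks[0][0].x
        )
        np.testing.assert_array_equal(
            a[1].sperm_tracks[2][1].y, b[1].sperm_tracks[2][1].y
        )
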