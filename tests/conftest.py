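"""Shared fixtures: rendered fixtures and the default simulated cohort."""

from __future__ import annotations

import numpy as np
import pytest

import mucotrack as mt


def render_single_spot(
    x: float,
    y: float,
    image_size: tuple[int, int] = (64, 64),
    psf_sigma: float = 2.0,
    spot_aspect: float = 1.0,
    heading: tuple[float, float] = (1.0, 0.0),
) -> np.ndarray:
    """One noiseless frame with a single Gaussian spot at (x, y) pixels.

    ``heading`` orients the major axis when the spot is elongated (the
    renderer derives orientation from motion, so the helper track moves
    slightly along that direction).
    """
    hx, hy = heading
    track = mt.Trajectory(
        particle_id=0,
        frames=[0, 1],
        x=[x, x + 0.001 * hx],
        y=[y, y + 0.001 * hy],
        frame_rate=1.0,
        units="um",
    )
    render = mt.RenderConfig(
        image_size=image_size,
        pixel_size=1.0,
        psf_sigma=psf_sigma,
        noise_model="none",
        spot_aspect=spot_aspect,
    )
    stack = mt.render_stack([track], render, frame_rate=1.0)
    return stack.frames[0]


def well_separated_bead_tracks(
    n: int = 4,
    viscosity: float = 1e-2,
    duration: float = 3.0,
    field_um: float = 12.8,
    seed: int = 0,
) -> tuple[list[mt.Trajectory], np.ndarray]:
    """Noiseless bead tracks started on a grid with wide margins.

    Returns (tracks, true_positions) where positions have shape
    (n, n_frames, 2) in um. Used for render -> detect -> link round
    trips where ground-truth pairing must be unambiguous.
    """
    cfg = mt.BeadSimConfig(
        viscosity=viscosity,
        n_particles=n,
        duration=duration,
        frame_rate=30.0,
        localization_noise_sd=0.0,
        seed=seed,
    )
    tracks, truth = mt.simulate_brownian_tracks(cfg)
    side = int(np.ceil(np.sqrt(n)))
    margin = field_um / (side + 1)
    out_tracks = []
    positions = truth.positions.copy()
    for i, t in enumerate(tracks):
        ox = margin * (1 + i % side)
        oy = margin * (1 + i // side)
        out_tracks.append(
            mt.Trajectory(
                particle_id=t.particle_id,
                frames=t.frames,
                x=t.x + ox,
                y=t.y + oy,
                frame_rate=t.frame_rate,
                units="um",
            )
        )
        positions[i, :, 0] += ox
        positions[i, :, 1] += oy
    return out_tracks, positions


@pytest.fixture(scope="session")
def default_cohort():
    """The default simulated cohort: 6 animals x 8 half-fold dilutions."""
    points = mt.simulate_dilution_series(6, mt.DEFAULT_DILUTIONS, seed=42)
    return points, mt.process_dilution_series(points)
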