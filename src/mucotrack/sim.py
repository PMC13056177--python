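"""Physics-grounded simulators for the two measurement regimes.

Two kinds of particle dynamics are generated, matching the acquisition
settings of the paired mucus assays:

* thermal diffusion of 1 um tracer beads in a fluid of known viscosity
  (10 s movies at 30 fps) — ground truth for the microrheology chain;
* progressive sperm swimming with lateral head oscillation, whose median
  speed scales with relative mucus concentration ``c`` as a power law
  ``v ~ c**(-beta)`` (5 s movies at 20 fps) — ground truth for the
  kinematics chain.

Both can be rendered into synthetic microscopy movies (Gaussian spots,
camera noise) so the detection/linking stages are testable end to end
without any external data.

Brownian increments are exact at any time step, so the dynamics use the
frame interval directly with no sub-stepping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core import ImageStack, Trajectory

__all__ = [
    "RheoParams",
    "BeadSimConfig",
    "SwimmerSimConfig",
    "RenderConfig",
    "GroundTruth",
    "DilutionSimPoint",
    "stokes_einstein_D",
    "simulate_brownian_tracks",
    "simulate_swimmer_tracks",
    "render_stack",
    "simulate_dilution_series",
]

BOLTZMANN = 1.380649e-23  # J/K, exact (SI)


@dataclass(frozen=True)
class RheoParams:
    """Physical parameters entering the Stokes–Einstein relation.

    temperature : K. The measurement temperature is a required assumption
        of the method (diffusivity and moduli scale linearly with T);
        default 293.15 K, consistent with a water-like buffer of
        viscosity 1e-3 Pa s.
    bead_radius : m. Default 0.5e-6 (1 um diameter polystyrene tracers).
    """

    temperature: float = 293.15
    bead_radius: float = 0.5e-6
    boltzmann_constant: float = BOLTZMANN

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        if self.bead_radius <= 0:
            raise ValueError("bead_radius must be positive (metres)")
        if self.boltzmann_constant <= 0:
            raise ValueError("boltzmann_constant must be positive")


def stokes_einstein_D(params: RheoParams, viscosity: float) -> float:
    """Stokes–Einstein diffusion coefficient, in um^2/s.

    D = k_B T / (6 pi eta a) for a sphere of radius ``a`` in a Newtonian
    fluid of viscosity ``eta`` (Pa s).
    """
    if viscosity <= 0:
        raise ValueError("viscosity must be positive (Pa s)")
    d_m2_s = (params.boltzmann_constant * params.temperature) / (
        6.0 * math.pi * viscosity * params.bead_radius
    )
    return d_m2_s * 1e12  # m^2/s -> um^2/s


@dataclass(frozen=True)
class BeadSimConfig:
    """Settings for a simulated bead-diffusion movie.

    Defaults follow the bead acquisition protocol: 10 s at 30 fps.
    ``localization_noise_sd`` (um) is added to the *reported* positions
    only, emulating centroiding error; the ground truth keeps the true
    positions. ``drift_velocity`` (um/s per axis) adds a constant
    advective component, for exercising drift correction.
    """

    viscosity: float
    rheo: RheoParams = RheoParams()
    n_particles: int = 30
    duration: float = 10.0
    frame_rate: float = 30.0
    localization_noise_sd: float = 0.02
    drift_velocity: tuple[float, float] = (0.0, 0.0)
    spawn_extent: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.viscosity <= 0:
            raise ValueError("viscosity must be positive (Pa s)")
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if self.duration <= 0 or self.frame_rate <= 0:
            raise ValueError("duration and frame_rate must be positive")
        if round(self.duration * self.frame_rate) < 1:
            raise ValueError("duration x frame_rate must cover at least 2 frames")
        if self.localization_noise_sd < 0:
            raise ValueError("localization_noise_sd must be >= 0")

    @property
    def diffusion_coefficient(self) -> float:
        """D in um^2/s implied by the viscosity and rheo parameters."""
        return stokes_einstein_D(self.rheo, self.viscosity)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate)) + 1


@dataclass(frozen=True)
class SwimmerSimConfig:
    """Settings for a simulated progressive-swimmer movie.

    The median progressive speed is ``base_speed * c**(-concentration_exponent)``
    where ``c = relative_concentration`` (1 for neat mucus, 1/dilution
    otherwise): diluting the mucus speeds the swimmers up along a power
    law. Individual speeds are drawn lognormal around that median with
    ``speed_dispersion`` expressed as the standard deviation in log10
    units. The path is a persistent heading (rotational diffusion with
    correlation time ``heading_persistence``) plus a sinusoidal lateral
    head displacement of amplitude ``wobble_amplitude``.

    Defaults follow the sperm acquisition protocol: 5 s at 20 fps.
    """

    base_speed: float = 10.0
    concentration_exponent: float = 0.5
    relative_concentration: float = 1.0
    speed_dispersion: float = 0.15
    wobble_amplitude: float = 2.0
    wobble_frequency: float = 2.0
    heading_persistence: float = 50.0
    n_sperm: int = 30
    duration: float = 5.0
    frame_rate: float = 20.0
    localization_noise_sd: float = 0.0
    spawn_extent: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_speed <= 0:
            raise ValueError("base_speed must be positive (um/s)")
        if not (0.0 < self.relative_concentration <= 1.0):
            raise ValueError("relative_concentration must lie in (0, 1]")
        if self.speed_dispersion < 0 or self.wobble_amplitude < 0:
            raise ValueError("speed_dispersion and wobble_amplitude must be >= 0")
        if self.wobble_frequency <= 0 or self.heading_persistence <= 0:
            raise ValueError("wobble_frequency and heading_persistence must be positive")
        if self.n_sperm < 1:
            raise ValueError("n_sperm must be >= 1")
        if self.duration <= 0 or self.frame_rate <= 0:
            raise ValueError("duration and frame_rate must be positive")

    @property
    def median_speed(self) -> float:
        """Median progressive speed implied by the concentration, um/s."""
        return self.base_speed * self.relative_concentration ** (
            -self.concentration_exponent
        )

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate)) + 1


@dataclass(frozen=True)
class RenderConfig:
    """Camera/optics stand-in for rendering tracks into movies.

    Spots are 2-D Gaussians of sd ``psf_sigma`` pixels and peak amplitude
    ``spot_intensity`` above a flat ``background``. ``spot_aspect`` > 1
    elongates spots along the direction of motion (sperm heads);
    eccentric spots are what the shape filters act on.
    """

    image_size: tuple[int, int] = (128, 128)
    pixel_size: float = 0.2
    psf_sigma: float = 2.0
    spot_intensity: float = 180.0
    background: float = 12.0
    noise_model: str = "gaussian"
    noise_sd: float = 2.0
    bit_depth: int = 16
    spot_aspect: float = 1.0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.psf_sigma <= 0 or self.spot_intensity <= 0:
            raise ValueError("pixel_size, psf_sigma and spot_intensity must be positive")
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ValueError("noise_model must be one of none|gaussian|poisson")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.spot_aspect < 1.0:
            raise ValueError("spot_aspect must be >= 1")


@dataclass
class GroundTruth:
    """Oracle record for a simulated movie.

    positions : (n_particles, n_frames, 2) true (x, y) in um, noise-free.
    speeds : (n_particles,) true progressive speeds in um/s (zeros for beads).
    config : the simulation config that produced it.
    """

    positions: np.ndarray
    speeds: np.ndarray
    config: object

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("ground-truth positions must be finite")


def _tracks_from_positions(
    observed: np.ndarray, frame_rate: float
) -> list[Trajectory]:
    frames = np.arange(observed.shape[1])
    return [
        Trajectory(
            particle_id=i,
            frames=frames,
            x=observed[i, :, 0],
            y=observed[i, :, 1],
            frame_rate=frame_rate,
            units="um",
        )
        for i in range(observed.shape[0])
    ]


def simulate_brownian_tracks(
    config: BeadSimConfig,
) -> tuple[list[Trajectory], GroundTruth]:
    """Simulate thermal bead diffusion.

    Per axis, position increments over one frame interval are i.i.d.
    Gaussian with variance ``2 D dt`` (exact for free diffusion at any
    dt). Constant drift, if configured, is added to the true positions;
    localization noise, if configured, perturbs only the reported
    positions. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    n, t = config.n_particles, config.n_frames
    dt = 1.0 / config.frame_rate
    d = config.diffusion_coefficient

    if config.spawn_extent is not None:
        start = rng.uniform(
            low=(0.0, 0.0), high=config.spawn_extent, size=(n, 2)
        )
    else:
        start = np.zeros((n, 2))

    steps = rng.normal(0.0, math.sqrt(2.0 * d * dt), size=(n, t - 1, 2))
    true = np.empty((n, t, 2))
    true[:, 0] = start
    true[:, 1:] = start[:, None, :] + np.cumsum(steps, axis=1)
    drift = np.asarray(config.drift_velocity, dtype=float)
    if np.any(drift != 0.0):
        times = np.arange(t) * dt
        true = true + times[None, :, None] * drift[None, None, :]

    observed = true
    if config.localization_noise_sd > 0:
        observed = true + rng.normal(
            0.0, config.localization_noise_sd, size=true.shape
        )

    truth = GroundTruth(positions=true, speeds=np.zeros(n), config=config)
    return _tracks_from_positions(observed, config.frame_rate), truth


def simulate_swimmer_tracks(
    config: SwimmerSimConfig,
) -> tuple[list[Trajectory], GroundTruth]:
    """Simulate progressively motile swimmers.

    Each swimmer draws a progressive speed lognormal around the
    concentration-scaled median, picks a uniform initial heading, and
    advances along a centreline whose heading diffuses rotationally with
    correlation time ``heading_persistence``; a sinusoidal lateral
    displacement (amplitude ``wobble_amplitude``, random phase) is
    superimposed perpendicular to the instantaneous heading, emulating
    the head wobble that CASA summarises as ALH.
    """
    rng = np.random.default_rng(config.seed)
    n, t = config.n_sperm, config.n_frames
    dt = 1.0 / config.frame_rate

    median = config.median_speed
    if config.speed_dispersion > 0:
        speeds = median * 10.0 ** rng.normal(0.0, config.speed_dispersion, size=n)
    else:
        speeds = np.full(n, median)

    if config.spawn_extent is not None:
        start = rng.uniform(low=(0.0, 0.0), high=config.spawn_extent, size=(n, 2))
    else:
        start = np.zeros((n, 2))

    theta0 = rng.uniform(0.0, 2.0 * math.pi, size=n)
    if math.isfinite(config.heading_persistence):
        dtheta_sd = math.sqrt(2.0 * dt / config.heading_persistence)
        dtheta = rng.normal(0.0, dtheta_sd, size=(n, t - 1))
    else:
        dtheta = np.zeros((n, t - 1))
    theta = np.empty((n, t))
    theta[:, 0] = theta0
    theta[:, 1:] = theta0[:, None] + np.cumsum(dtheta, axis=1)

    heading = np.stack([np.cos(theta), np.sin(theta)], axis=-1)  # (n, t, 2)
    # centreline: integrate v * heading over frame intervals
    step_vec = speeds[:, None, None] * dt * heading[:, :-1, :]
    centre = np.empty((n, t, 2))
    centre[:, 0] = start
    centre[:, 1:] = start[:, None, :] + np.cumsum(step_vec, axis=1)

    if config.wobble_amplitude > 0:
        phase = rng.uniform(0.0, 2.0 * math.pi, size=n)
        times = np.arange(t) * dt
        lateral = config.wobble_amplitude * np.sin(
            2.0 * math.pi * config.wobble_frequency * times[None, :] + phase[:, None]
        )
        perp = np.stack([-np.sin(theta), np.cos(theta)], axis=-1)
        true = centre + lateral[:, :, None] * perp
    else:
        true = centre

    observed = true
    if config.localization_noise_sd > 0:
        observed = true + rng.normal(
            0.0, config.localization_noise_sd, size=true.shape
        )

    truth = GroundTruth(positions=true, speeds=speeds, config=config)
    return _tracks_from_positions(observed, config.frame_rate), truth


def render_stack(
    tracks: Sequence[Trajectory],
    render: RenderConfig,
    frame_rate: float,
    seed: int = 0,
) -> ImageStack:
    """Render trajectories into a synthetic microscopy movie.

    Each particle is drawn as a 2-D Gaussian spot (sd ``psf_sigma`` px)
    centred at its um position divided by ``pixel_size``. With
    ``spot_aspect`` > 1 the spot's major axis (sd ``aspect * psf_sigma``)
    is aligned with the particle's instantaneous direction of motion.
    Particles outside the field of view are silently clipped. Camera
    noise is applied per the noise model and intensities are clipped to
    the bit depth.
    """
    h, w = render.image_size
    n_frames = 2
    for tr in tracks:
        if not (np.all(np.isfinite(tr.x)) and np.all(np.isfinite(tr.y))):
            raise ValueError(f"track {tr.particle_id} has non-finite positions")
        n_frames = max(n_frames, int(tr.frames[-1]) + 1)

    frames = np.full((n_frames, h, w), float(render.background))
    sig_minor = render.psf_sigma
    sig_major = render.psf_sigma * render.spot_aspect
    half = int(math.ceil(4.0 * sig_major)) + 1

    for tr in tracks:
        xs = tr.x / render.pixel_size if tr.units == "um" else tr.x
        ys = tr.y / render.pixel_size if tr.units == "um" else tr.y
        # orientation from local displacement (for elongated spots)
        dx = np.gradient(xs)
        dy = np.gradient(ys)
        for k, f in enumerate(tr.frames):
            cx, cy = xs[k], ys[k]
            if not (-half < cx < w + half and -half < cy < h + half):
                continue  # out of field: clipped
            x0 = max(int(math.floor(cx)) - half, 0)
            x1 = min(int(math.floor(cx)) + half + 1, w)
            y0 = max(int(math.floor(cy)) - half, 0)
            y1 = min(int(math.floor(cy)) + half + 1, h)
            if x0 >= x1 or y0 >= y1:
                continue
            yy, xx = np.mgrid[y0:y1, x0:x1]
            u = xx - cx
            v = yy - cy
            if render.spot_aspect != 1.0 and (dx[k] != 0.0 or dy[k] != 0.0):
                ang = math.atan2(dy[k], dx[k])
                ca, sa = math.cos(ang), math.sin(ang)
                a = ca * u + sa * v   # along motion
                b = -sa * u + ca * v  # across motion
            else:
                a, b = u, v
            spot = render.spot_intensity * np.exp(
                -0.5 * (a / sig_major) ** 2 - 0.5 * (b / sig_minor) ** 2
            )
            frames[f, y0:y1, x0:x1] += spot

    rng = np.random.default_rng(seed)
    if render.noise_model == "gaussian" and render.noise_sd > 0:
        frames = frames + rng.normal(0.0, render.noise_sd, size=frames.shape)
    elif render.noise_model == "poisson":
        frames = rng.poisson(np.clip(frames, 0, None)).astype(float)

    vmax = 2**render.bit_depth - 1
    frames = np.clip(np.round(frames), 0, vmax)
    dtype = np.uint8 if render.bit_depth == 8 else np.uint16
    return ImageStack(
        frames=frames.astype(dtype),
        frame_rate=frame_rate,
        pixel_size=render.pixel_size,
        metadata={"seed": seed, "render": render},
    )


@dataclass
class DilutionSimPoint:
    """One simulated animal x dilution condition with replicate movies.

    ``bead_tracks`` and ``sperm_tracks`` hold one list of trajectories
    per technical replicate (beads in duplicate, sperm in triplicate by
    default, matching the assay protocol).
    """

    animal: int
    dilution: float
    concentration: float
    true_viscosity: float
    true_median_speed: float
    bead_tracks: list[list[Trajectory]]
    sperm_tracks: list[list[Trajectory]]
    bead_truths: list[GroundTruth] = field(default_factory=list)
    sperm_truths: list[GroundTruth] = field(default_factory=list)


def simulate_dilution_series(
    n_animals: int,
    dilution_factors: Sequence[float],
    bead_cfg_template: BeadSimConfig | None = None,
    swimmer_cfg_template: SwimmerSimConfig | None = None,
    rheology_scaling_exponent: float = 3.0,
    eta_buffer: float = 1e-3,
    eta_neat: float = 0.1,
    animal_sd_log10: float = 0.2,
    n_bead_replicates: int = 2,
    n_sperm_replicates: int = 3,
    seed: int = 0,
) -> list[DilutionSimPoint]:
    """Simulate a paired half-fold dilution cohort.

    For each animal and dilution factor ``d`` (relative concentration
    ``c = 1/d``) the sample viscosity follows

        eta(c) = eta_buffer + (eta_neat - eta_buffer) * c**rheology_scaling_exponent

    interpolating between the neat-mucus viscosity and the buffer value
    as the sample is diluted (the steep default exponent reflects the
    strong concentration dependence typical of mucus). Sperm speeds
    follow the swimmer power law at the same ``c``. Animal-level
    heterogeneity multiplies each animal's ``eta_neat`` and ``base_speed``
    by independent lognormal factors (sd ``animal_sd_log10`` in log10
    units). Bead movies run in technical duplicate and sperm movies in
    triplicate by default. Deterministic for a fixed seed.
    """
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    if len(dilution_factors) == 0:
        raise ValueError("dilution_factors must be non-empty")
    if any(d < 1 for d in dilution_factors):
        raise ValueError("dilution factors must be >= 1")
    if eta_buffer <= 0 or eta_neat <= eta_buffer:
        raise ValueError("need 0 < eta_buffer < eta_neat")

    bead_tpl = bead_cfg_template or BeadSimConfig(viscosity=eta_buffer)
    swim_tpl = swimmer_cfg_template or SwimmerSimConfig()

    root = np.random.SeedSequence(seed)
    effect_rng = np.random.default_rng(root.spawn(1)[0])
    eta_factors = 10.0 ** effect_rng.normal(0.0, animal_sd_log10, size=n_animals)
    speed_factors = 10.0 ** effect_rng.normal(0.0, animal_sd_log10, size=n_animals)

    child_seeds = iter(root.generate_state(2 * n_animals * len(dilution_factors) *
                                           (n_bead_replicates + n_sperm_replicates) + 16) % (2**31))

    points: list[DilutionSimPoint] = []
    for a in range(n_animals):
        eta_neat_a = eta_buffer + (eta_neat * eta_factors[a] - eta_buffer)
        for d in dilution_factors:
            c = 1.0 / d
            eta = eta_buffer + (eta_neat_a - eta_buffer) * c**rheology_scaling_exponent
            bead_reps, bead_truths = [], []
            for _ in range(n_bead_replicates):
                cfg = replace(bead_tpl, viscosity=eta, seed=int(next(child_seeds)))
                tracks, truth = simulate_brownian_tracks(cfg)
                bead_reps.append(tracks)
                bead_truths.append(truth)
            sperm_reps, sperm_truths = [], []
            base_a = swim_tpl.base_speed * speed_factors[a]
            for _ in range(n_sperm_replicates):
                cfg = replace(
                    swim_tpl,
                    base_speed=base_a,
                    relative_concentration=c,
                    seed=int(next(child_seeds)),
                )
                tracks, truth = simulate_swimmer_tracks(cfg)
                sperm_reps.append(tracks)
                sperm_truths.append(truth)
            points.append(
                DilutionSimPoint(
                    animal=a,
                    dilution=float(d),
                    concentration=c,
                    true_viscosity=eta,
                    true_median_speed=base_a * c ** (-swim_tpl.concentration_exponent),
                    bead_tracks=bead_reps,
                    sperm_tracks=sperm_reps,
                    bead_truths=bead_truths,
                    sperm_truths=sperm_truths,
                )
            )
    return points
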