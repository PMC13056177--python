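"""End-to-end orchestration: simulate -> track -> rheology/kinematics -> correlate.

``run_pipeline`` executes one acquisition mode (bead or sperm) from a
movie (simulated and rendered, or loaded from disk) through detection,
linking and the mode's summary statistic, persisting every stage's
outputs. ``process_dilution_series`` runs the paired cohort analysis
that relates complex viscosity to sperm velocity across dilutions.

All randomness flows from the single config seed; reruns with the same
config produce bit-identical CSV outputs.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import io as mio
from .analysis import (
    AnalysisConfig,
    CorrelationResult,
    DilutionPoint,
    PowerLawFit,
    aggregate_dilution_point,
    correlate_log_values,
    fit_power_law,
)
from .core import ImageStack, Trajectory
from .kinematics import summarize_kinematics, track_kinematics
from .microrheology import OMEGA_REF, bead_tracks_to_eta_star
from .sim import (
    BeadSimConfig,
    DilutionSimPoint,
    RenderConfig,
    RheoParams,
    SwimmerSimConfig,
    render_stack,
    simulate_brownian_tracks,
    simulate_swimmer_tracks,
)
from .tracking import (
    BEAD_PARAMS,
    SPERM_PARAMS,
    DetectionParams,
    filter_trajectories,
    link_features,
    locate_stack,
)

__all__ = ["RunConfig", "run_pipeline", "process_dilution_series", "DEFAULT_DILUTIONS"]

logger = logging.getLogger(__name__)

#: Half-fold dilution ladder out to 1:128.
DEFAULT_DILUTIONS = (1, 2, 4, 8, 16, 32, 64, 128)

# per-mode defaults: (detection, frame_rate, search_range_px, memory, min_duration_s)
_MODE_DEFAULTS = {
    "bead": (BEAD_PARAMS, 30.0, 5.0, 3, 0.0),
    "sperm": (SPERM_PARAMS, 20.0, 15.0, 0, 1.0),
}


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Mode-specific defaults (detection diameter/eccentricity, frame rate,
    linking and duration-filter settings) are applied by
    :meth:`for_mode`; every field can be overridden explicitly.
    """

    mode: str
    seed: int = 0
    out_dir: str | Path | None = None
    input_stack: str | Path | None = None
    detection: DetectionParams = field(default_factory=lambda: BEAD_PARAMS)
    search_range: float = 5.0
    memory: int = 3
    min_duration: float = 0.0
    frame_rate: float = 30.0
    pixel_size: float = 0.2
    rheo: RheoParams = field(default_factory=RheoParams)
    omega_ref: float = OMEGA_REF
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    render: RenderConfig = field(default_factory=RenderConfig)
    sim_viscosity: float = 1e-3
    sim_n_particles: int = 12
    sim_duration: float | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in _MODE_DEFAULTS:
            raise ValueError(
                f"invalid mode {self.mode!r}; valid modes: {sorted(_MODE_DEFAULTS)}"
            )

    @classmethod
    def for_mode(cls, mode: str, **overrides) -> "RunConfig":
        if mode not in _MODE_DEFAULTS:
            raise ValueError(f"invalid mode {mode!r}; valid modes: {sorted(_MODE_DEFAULTS)}")
        det, fr, sr, mem, mind = _MODE_DEFAULTS[mode]
        base = dict(
            mode=mode, detection=det, frame_rate=fr, search_range=sr,
            memory=mem, min_duration=mind,
        )
        base.update(overrides)
        return cls(**base)


def _simulate_stack(config: RunConfig) -> tuple[ImageStack, list[Trajectory]]:
    """Simulate tracks for the configured mode and render them."""
    h, w = config.render.image_size
    extent = (w * config.render.pixel_size, h * config.render.pixel_size)
    if config.mode == "bead":
        sim_cfg = BeadSimConfig(
            viscosity=config.sim_viscosity,
            rheo=config.rheo,
            n_particles=config.sim_n_particles,
            duration=config.sim_duration or 10.0,
            frame_rate=config.frame_rate,
            spawn_extent=extent,
            seed=config.seed,
        )
        tracks, _ = simulate_brownian_tracks(sim_cfg)
    else:
        sim_cfg = SwimmerSimConfig(
            n_sperm=config.sim_n_particles,
            duration=config.sim_duration or 5.0,
            frame_rate=config.frame_rate,
            spawn_extent=extent,
            seed=config.seed,
        )
        tracks, _ = simulate_swimmer_tracks(sim_cfg)
    stack = render_stack(tracks, config.render, config.frame_rate, seed=config.seed)
    return stack, tracks


def run_pipeline(config: RunConfig) -> dict:
    """Execute the stage chain for one movie and return the report dict.

    Stages: acquire (load or simulate+render) -> detect -> link ->
    duration-filter -> mode summary (ensemble eta* at the reference
    frequency for beads; kinematics summaries for sperm). When
    ``out_dir`` is set, detections, trajectories and the report are
    persisted along with the config and seed.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    stage = "acquire"
    try:
        detection = config.detection
        if config.input_stack is not None:
            stack = mio.read_image_stack(
                config.input_stack, config.frame_rate, config.pixel_size
            )
        else:
            stack, _truth_tracks = _simulate_stack(config)
            if out:
                mio.write_image_stack(stack, out / f"{config.mode}_stack.tif")
            if detection.min_mass == 0 and config.render.noise_model != "none":
                # the renderer knows its spot mass; a quarter of it cleanly
                # separates real spots from camera-noise maxima
                spot_mass = (
                    2.0 * math.pi * config.render.psf_sigma**2
                    * config.render.spot_aspect * config.render.spot_intensity
                )
                detection = dataclasses.replace(detection, min_mass=0.25 * spot_mass)

        stage = "detect"
        detections = locate_stack(stack, detection)
        if out:
            mio.write_detections_csv(detections, out / f"{config.mode}_detections.csv")

        stage = "link"
        tracks = link_features(
            detections, config.search_range, config.memory, frame_rate=stack.frame_rate
        )
        tracks = filter_trajectories(tracks, config.min_duration)
        tracks_um = [t.to_um(stack.pixel_size) for t in tracks]
        if out:
            mio.write_trajectories_csv(tracks_um, out / f"{config.mode}_trajectories.csv")

        stage = "summarize"
        report: dict = {
            "mode": config.mode,
            "seed": config.seed,
            "n_frames": stack.n_frames,
            "n_detections": int(sum(len(d) for d in detections)),
            "n_tracks": len(tracks_um),
            "frame_rate_hz": stack.frame_rate,
            "pixel_size_um": stack.pixel_size,
            "assumed_temperature_K": config.rheo.temperature,
        }
        if config.mode == "bead":
            eta, n_used = bead_tracks_to_eta_star(
                tracks_um, config.rheo, omega_ref=config.omega_ref
            )
            report["eta_star_Pa_s"] = eta
            report["omega_ref_rad_s"] = config.omega_ref
            report["n_tracks_used"] = n_used
        else:
            records = [track_kinematics(t) for t in tracks_um]
            summ = summarize_kinematics(
                records, stat=config.analysis.stat, log10=False
            )
            log_summ = summarize_kinematics(
                records, stat=config.analysis.stat, log10=True
            )
            report["vsl_um_s"] = summ.value
            report["log10_vsl"] = log_summ.value
            report["n_tracks_used"] = summ.n_used
        if out:
            mio.write_json(report, out / f"{config.mode}_report.json")
            mio.dump_config_yaml(_config_to_dict(config), out / "config.yaml")
        return report
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {err}") from err


def _config_to_dict(config: RunConfig) -> dict:
    def convert(v):
        if dataclasses.is_dataclass(v) and not isinstance(v, type):
            return {k: convert(x) for k, x in dataclasses.asdict(v).items()}
        if isinstance(v, Path):
            return str(v)
        if isinstance(v, tuple):
            return list(v)
        return v

    return {k: convert(v) for k, v in dataclasses.asdict(config).items()}


def process_dilution_series(
    points: Sequence[DilutionSimPoint],
    rheo: RheoParams | None = None,
    analysis: AnalysisConfig = AnalysisConfig(),
    omega_ref: float = OMEGA_REF,
    min_duration: float = 1.0,
) -> dict:
    """Paired cohort analysis over simulated dilution points.

    Per replicate: bead tracks run through the MSD -> GSER chain to an
    ensemble eta* at the reference frequency; sperm tracks pass the
    duration filter, then each track's VSL is computed and the replicate
    is summarised by its median. Per point: replicate log10 values are
    aggregated (median by default). The report holds the pooled Pearson
    correlation of log10 velocity vs log10 eta*, and the power-law fit
    of velocity against relative concentration.
    """
    rheo = rheo or RheoParams()
    dpoints: list[DilutionPoint] = []
    for pt in points:
        etas = []
        for rep_tracks in pt.bead_tracks:
            eta, _ = bead_tracks_to_eta_star(rep_tracks, rheo, omega_ref=omega_ref)
            etas.append(eta)
        vels = []
        for rep_tracks in pt.sperm_tracks:
            kept = filter_trajectories(rep_tracks, min_duration)
            if not kept:
                continue
            records = [track_kinematics(t) for t in kept]
            vels.append(float(np.median([r.vsl for r in records])))
        dpoints.append(
            DilutionPoint(
                animal=pt.animal,
                dilution=pt.dilution,
                eta_star_replicates=etas,
                velocity_replicates=vels,
            )
        )

    aggregated = [aggregate_dilution_point(p, analysis) for p in dpoints]
    usable = [a for a in aggregated if a is not None]
    corr = correlate_log_values(usable)

    # median velocity and eta* per dilution across animals/replicates
    dilutions = sorted({p.dilution for p in dpoints})
    med_v, med_eta = {}, {}
    for d in dilutions:
        vs = [a.log_velocity for a in usable if a.dilution == d]
        es = [a.log_eta_star for a in usable if a.dilution == d]
        med_v[d] = 10.0 ** float(np.median(vs))
        med_eta[d] = 10.0 ** float(np.median(es))
    power = fit_power_law([1.0 / d for d in dilutions], [med_v[d] for d in dilutions])

    return {
        "points": dpoints,
        "aggregated": usable,
        "correlation": corr,
        "velocity_power_law": power,
        "median_velocity_by_dilution": med_v,
        "median_eta_star_by_dilution": med_eta,
    }
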