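"""CASA-style sperm kinematics from trajectories.

Standard computer-assisted sperm analysis metrics, computed per track:

* VSL — straight-line velocity: net first-to-last displacement over the
  recorded duration;
* VCL — curvilinear velocity: summed point-to-point path length over
  duration;
* VAP — average-path velocity: path length of a centred moving-average
  smoothed path over duration;
* LIN = VSL/VCL, STR = VSL/VAP;
* ALH — amplitude of lateral head displacement: twice the mean absolute
  perpendicular deviation of the raw path from the average path (a
  ``2 x max`` variant is available, as CASA vendors differ).

All velocities are in um/s, ALH in um.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import Trajectory

__all__ = ["KinematicsRecord", "SampleSummary", "track_kinematics", "summarize_kinematics"]

logger = logging.getLogger(__name__)


@dataclass
class KinematicsRecord:
    """Per-track motility metrics."""

    track_id: int
    duration: float
    vsl: float
    vcl: float
    vap: float
    lin: float
    str_: float
    alh: float


@dataclass
class SampleSummary:
    """Central tendency of a kinematic metric over a sample's tracks."""

    value: float
    stat: str
    log10: bool
    n_used: int
    n_excluded: int
    spread: float  # sd of the (transformed) values


def _moving_average_path(pos: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average, windows shrunk symmetrically at the edges.

    Keeping the window symmetric (half-width min(half, i, n-1-i)) pins
    the smoothed endpoints to the raw ones, so a straight path has
    VAP = VCL exactly instead of being shortened by edge truncation.
    """
    n = len(pos)
    half = window // 2
    idx = np.arange(n)
    half_i = np.minimum(half, np.minimum(idx, n - 1 - idx))
    csum = np.vstack([[0.0, 0.0], np.cumsum(pos, axis=0)])
    lo = idx - half_i
    hi = idx + half_i + 1
    return (csum[hi] - csum[lo]) / (hi - lo)[:, None]


def track_kinematics(
    track: Trajectory,
    pixel_size: float | None = None,
    vap_window: int = 5,
    alh_mode: str = "mean",
) -> KinematicsRecord:
    """Compute the CASA metrics for one trajectory.

    ``vap_window`` is the moving-average length in frames (default 5,
    about one wobble period at 20 fps); edges use truncated windows.
    ``alh_mode`` selects twice the mean ("mean") or twice the maximum
    ("max") absolute lateral deviation.
    """
    if alh_mode not in ("mean", "max"):
        raise ValueError("alh_mode must be 'mean' or 'max'")
    if vap_window < 1:
        raise ValueError("vap_window must be >= 1")
    if track.units == "px":
        if pixel_size is None:
            raise ValueError("pixel-unit track needs pixel_size for um conversion")
        track = track.to_um(pixel_size)

    duration = track.duration
    if duration <= 0:
        raise ValueError("track duration must be positive")
    pos = track.positions

    vsl = float(np.linalg.norm(pos[-1] - pos[0])) / duration
    steps = np.diff(pos, axis=0)
    vcl = float(np.linalg.norm(steps, axis=1).sum()) / duration

    avg = _moving_average_path(pos, vap_window)
    vap = float(np.linalg.norm(np.diff(avg, axis=0), axis=1).sum()) / duration

    # lateral deviation: component of (raw - average) perpendicular to the
    # local tangent of the average path
    tangent = np.gradient(avg, axis=0)
    norm = np.linalg.norm(tangent, axis=1)
    resid = pos - avg
    perp = np.where(
        norm > 1e-12,
        np.abs(resid[:, 0] * tangent[:, 1] - resid[:, 1] * tangent[:, 0])
        / np.where(norm > 1e-12, norm, 1.0),
        np.linalg.norm(resid, axis=1),
    )
    alh = 2.0 * float(perp.mean() if alh_mode == "mean" else perp.max())

    lin = vsl / vcl if vcl > 0 else 0.0
    str_ = vsl / vap if vap > 0 else 0.0
    return KinematicsRecord(
        track_id=track.particle_id,
        duration=duration,
        vsl=vsl,
        vcl=vcl,
        vap=vap,
        lin=lin,
        str_=str_,
        alh=alh,
    )


def summarize_kinematics(
    records: Sequence[KinematicsRecord],
    stat: str = "median",
    log10: bool = False,
    metric: str = "vsl",
) -> SampleSummary:
    """Central tendency of one metric across a sample's tracks.

    With ``log10`` the values are log10-transformed first; non-finite
    and (under log10) non-positive values are excluded and counted.
    """
    if len(records) == 0:
        raise ValueError("need at least one kinematics record")
    if stat not in ("median", "mean"):
        raise ValueError("stat must be 'median' or 'mean'")
    vals = np.array([getattr(r, metric if metric != "str" else "str_") for r in records])
    finite = np.isfinite(vals)
    if log10:
        finite &= vals > 0
    n_excl = int((~finite).sum())
    if n_excl:
        logger.info("excluded %d/%d non-finite or non-positive values", n_excl, len(vals))
    vals = vals[finite]
    if len(vals) == 0:
        raise ValueError("no usable values after exclusions")
    if log10:
        vals = np.log10(vals)
    value = float(np.median(vals) if stat == "median" else np.mean(vals))
    return SampleSummary(
        value=value,
        stat=stat,
        log10=log10,
        n_used=len(vals),
        n_excluded=n_excl,
        spread=float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
    )
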