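"""Feature detection and trajectory linking (Crocker–Grier scheme).

The detector band-passes each frame, takes local maxima above an
intensity percentile, refines each candidate to sub-pixel precision by
iterative masked centroiding, and filters candidates on integrated mass
and eccentricity. The two detection regimes differ only in their shape
parameters: beads use an 11 px feature diameter with eccentricity cutoff
0.3; sperm heads, being larger and elongated, use 17 px and 0.5.

The linker assigns detections frame to frame by minimising the total
squared displacement within a search range (solved exactly with the
Hungarian algorithm, birth/death moves priced at the squared search
range), with an optional gap-closing memory.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

from .core import ImageStack, Trajectory

__all__ = [
    "DetectionParams",
    "Detection",
    "bandpass_filter",
    "locate_features",
    "locate_stack",
    "link_features",
    "filter_trajectories",
    "BEAD_PARAMS",
    "SPERM_PARAMS",
]

logger = logging.getLogger(__name__)

# Hard cap on the linking cost matrix (n_prev * n_curr); beyond this the
# assignment is refused rather than silently slow.
_MAX_ASSIGNMENT_SIZE = 4_000_000


@dataclass(frozen=True)
class DetectionParams:
    """Shape and intensity filters for feature detection.

    feature_diameter : odd pixel extent of the centroiding mask
        (11 for beads, 17 for sperm heads).
    max_eccentricity : reject features more elongated than this
        (0.3 for beads, 0.5 for sperm heads).
    min_mass : minimum integrated (band-passed) intensity; 0 disables.
    noise_size : sd in pixels of the short-wavelength Gaussian blur.
    threshold_percentile : percentile of the band-passed image below
        which local maxima are ignored.
    """

    feature_diameter: int = 11
    max_eccentricity: float = 0.3
    min_mass: float = 0.0
    noise_size: float = 1.0
    threshold_percentile: float = 64.0

    def __post_init__(self) -> None:
        if self.feature_diameter < 3 or self.feature_diameter % 2 == 0:
            raise ValueError("feature_diameter must be an odd integer >= 3")
        if not (0.0 <= self.max_eccentricity < 1.0):
            raise ValueError("max_eccentricity must lie in [0, 1)")
        if self.min_mass < 0:
            raise ValueError("min_mass must be >= 0")
        if self.noise_size <= 0:
            raise ValueError("noise_size must be positive")
        if not (0.0 <= self.threshold_percentile <= 100.0):
            raise ValueError("threshold_percentile must lie in [0, 100]")


#: Detection defaults for the two acquisition regimes.
BEAD_PARAMS = DetectionParams(feature_diameter=11, max_eccentricity=0.3)
SPERM_PARAMS = DetectionParams(feature_diameter=17, max_eccentricity=0.5)


@dataclass
class Detection:
    """A localized feature in one frame (pixel units, sub-pixel x/y)."""

    frame: int
    x: float
    y: float
    mass: float
    size: float
    ecc: float


def bandpass_filter(
    frame: np.ndarray, noise_size: float, feature_diameter: int
) -> np.ndarray:
    """Band-pass an image for feature detection.

    Gaussian blur at the noise scale minus a boxcar background estimate
    at the feature scale; negative values are clipped to zero. A uniform
    image therefore maps to all zeros.
    """
    if feature_diameter <= noise_size:
        raise ValueError("feature_diameter must exceed noise_size")
    img = np.asarray(frame, dtype=float)
    smoothed = ndimage.gaussian_filter(img, noise_size, mode="reflect")
    background = ndimage.uniform_filter(img, feature_diameter, mode="reflect")
    return np.clip(smoothed - background, 0.0, None)


def _circular_mask(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return (xx**2 + yy**2) <= radius**2


def _refine(
    image: np.ndarray, cy: int, cx: int, radius: int
) -> tuple[float, float, float, float, float] | None:
    """Iterative masked-centroid refinement around an integer seed.

    Returns (x, y, mass, size, ecc) or None when the mask would leave
    the image or the masked intensity vanishes. Up to 10 iterations,
    moving the integer window whenever the centroid offset exceeds half
    a pixel; sub-pixel position is window centre plus final offset.
    """
    h, w = image.shape
    mask = _circular_mask(radius)
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]

    for _ in range(10):
        if not (radius <= cy < h - radius and radius <= cx < w - radius):
            return None
        win = image[cy - radius : cy + radius + 1, cx - radius : cx + radius + 1]
        masked = win * mask
        mass = masked.sum()
        if mass <= 0:
            return None
        off_x = float((masked * xx).sum() / mass)
        off_y = float((masked * yy).sum() / mass)
        if abs(off_x) <= 0.5 and abs(off_y) <= 0.5:
            break
        cx += int(np.clip(round(off_x), -1, 1))
        cy += int(np.clip(round(off_y), -1, 1))
    else:
        if not (radius <= cy < h - radius and radius <= cx < w - radius):
            return None
        win = image[cy - radius : cy + radius + 1, cx - radius : cx + radius + 1]
        masked = win * mask
        mass = masked.sum()
        if mass <= 0:
            return None
        off_x = float((masked * xx).sum() / mass)
        off_y = float((masked * yy).sum() / mass)

    # moments about the refined (sub-pixel) centre
    u = xx - off_x
    v = yy - off_y
    r2 = u**2 + v**2
    size = math.sqrt(float((masked * r2).sum() / mass))
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arctan2(v, u)
    c2 = float((masked * np.cos(2 * theta)).sum())
    s2 = float((masked * np.sin(2 * theta)).sum())
    centre_val = float(masked[radius, radius])
    denom = mass - centre_val
    ecc = math.sqrt(c2**2 + s2**2) / denom if denom > 0 else 0.0
    return cx + off_x, cy + off_y, float(mass), size, ecc


def locate_features(
    frame: np.ndarray, params: DetectionParams, frame_index: int = 0
) -> list[Detection]:
    """Detect particle-like features in a single frame.

    Pipeline: band-pass; local maxima above the threshold percentile;
    iterative sub-pixel centroid refinement within a circular mask of
    the feature diameter; mass/size/eccentricity from intensity moments;
    candidates failing ``min_mass`` or ``max_eccentricity`` removed;
    duplicates closer than one feature diameter merged keeping the
    larger mass (ties broken toward lower (y, x)).
    """
    img = np.asarray(frame, dtype=float)
    if min(img.shape) <= params.feature_diameter:
        raise ValueError("frame dimensions must exceed feature_diameter")
    bp = bandpass_filter(img, params.noise_size, params.feature_diameter)
    if not np.any(bp > 0):
        return []

    threshold = float(np.percentile(bp, params.threshold_percentile))
    # floor rejects numerically-positive residue in flat regions
    threshold = max(threshold, 1e-6 * float(bp.max()))
    radius = params.feature_diameter // 2
    maxima = (
        (ndimage.maximum_filter(bp, size=params.feature_diameter, mode="constant") == bp)
        & (bp > threshold)
    )
    # exclude a margin where the centroid mask cannot fit
    maxima[:radius, :] = maxima[-radius:, :] = False
    maxima[:, :radius] = maxima[:, -radius:] = False
    cand_y, cand_x = np.nonzero(maxima)

    refined: list[Detection] = []
    for cy, cx in zip(cand_y, cand_x):
        res = _refine(bp, int(cy), int(cx), radius)
        if res is None:
            continue
        x, y, mass, size, ecc = res
        refined.append(Detection(frame=frame_index, x=x, y=y, mass=mass, size=size, ecc=ecc))

    # merge duplicates closer than one feature diameter, keep larger mass
    refined.sort(key=lambda d: (-d.mass, d.y, d.x))
    kept: list[Detection] = []
    for det in refined:
        if all(
            (det.x - k.x) ** 2 + (det.y - k.y) ** 2 >= params.feature_diameter**2
            for k in kept
        ):
            kept.append(det)

    n_before = len(kept)
    kept = [
        d
        for d in kept
        if d.mass >= params.min_mass and d.ecc <= params.max_eccentricity
    ]
    if n_before != len(kept):
        logger.debug(
            "frame %d: %d/%d candidates removed by mass/eccentricity filters",
            frame_index, n_before - len(kept), n_before,
        )
    kept.sort(key=lambda d: (d.y, d.x))
    return kept


def locate_stack(stack: ImageStack, params: DetectionParams) -> list[list[Detection]]:
    """Run :func:`locate_features` on every frame of a stack."""
    out = [
        locate_features(stack.frames[t], params, frame_index=t)
        for t in range(stack.n_frames)
    ]
    logger.info(
        "located %d features across %d frames", sum(len(d) for d in out), stack.n_frames
    )
    return out


@dataclass
class _Active:
    pid: int
    x: float
    y: float
    last_frame: int
    frames: list[int] = field(default_factory=list)
    xs: list[float] = field(default_factory=list)
    ys: list[float] = field(default_factory=list)


def link_features(
    detections: Sequence[Sequence[Detection]],
    search_range: float,
    memory: int = 0,
    frame_rate: float = 1.0,
) -> list[Trajectory]:
    """Link per-frame detections into trajectories.

    Assignment between live particles and the next frame's detections
    minimises the total squared displacement; candidate links farther
    than ``search_range`` are forbidden, and leaving a particle
    unmatched (track end) or starting a new track each costs
    ``search_range**2``, so valid links are always preferred and
    competition is resolved globally. A particle unmatched for at most
    ``memory`` frames may resume its identity; its trajectory then has
    a gap. Detections must be grouped per frame in increasing frame
    order. Tracks with fewer than two points are discarded.
    """
    if search_range <= 0:
        raise ValueError("search_range must be positive")
    if memory < 0:
        raise ValueError("memory must be >= 0")

    next_id = 0
    live: list[_Active] = []
    finished: list[_Active] = []
    r2 = search_range**2

    for per_frame in detections:
        dets = list(per_frame)
        if dets and any(d.frame != dets[0].frame for d in dets):
            raise ValueError("each inner list must hold detections of a single frame")
        f = dets[0].frame if dets else None

        if f is not None:
            # retire particles lost for longer than the memory window
            still = []
            for p in live:
                if f - p.last_frame - 1 > memory:
                    finished.append(p)
                else:
                    still.append(p)
            live = still

            n_prev, n_cur = len(live), len(dets)
            if n_prev * n_cur > _MAX_ASSIGNMENT_SIZE:
                raise RuntimeError(
                    "linking problem too large; reduce search_range or particle density"
                )
            matched_prev = set()
            matched_cur = set()
            if n_prev and n_cur:
                big = 4.0 * r2  # finite stand-in for a forbidden link
                size = n_prev + n_cur
                cost = np.full((size, size), 0.0)
                px = np.array([p.x for p in live])
                py = np.array([p.y for p in live])
                dx = px[:, None] - np.array([d.x for d in dets])[None, :]
                dy = py[:, None] - np.array([d.y for d in dets])[None, :]
                d2 = dx**2 + dy**2
                d2[d2 > r2] = big
                cost[:n_prev, :n_cur] = d2
                cost[:n_prev, n_cur:] = big  # default: no death for wrong slot
                cost[n_prev:, :n_cur] = big
                cost[:n_prev, n_cur:][np.arange(n_prev), np.arange(n_prev)] = r2
                cost[n_prev:, :n_cur][np.arange(n_cur), np.arange(n_cur)] = r2
                rows, cols = linear_sum_assignment(cost)
                for i, j in zip(rows, cols):
                    if i < n_prev and j < n_cur and d2[i, j] <= r2:
                        p = live[i]
                        d = dets[j]
                        p.frames.append(d.frame)
                        p.xs.append(d.x)
                        p.ys.append(d.y)
                        p.x, p.y, p.last_frame = d.x, d.y, d.frame
                        matched_prev.add(i)
                        matched_cur.add(j)
            for j, d in enumerate(dets):
                if j not in matched_cur:
                    live.append(
                        _Active(
                            pid=next_id,
                            x=d.x,
                            y=d.y,
                            last_frame=d.frame,
                            frames=[d.frame],
                            xs=[d.x],
                            ys=[d.y],
                        )
                    )
                    next_id += 1

    finished.extend(live)
    tracks = [
        Trajectory(
            particle_id=p.pid,
            frames=np.array(p.frames),
            x=np.array(p.xs),
            y=np.array(p.ys),
            frame_rate=frame_rate,
            units="px",
        )
        for p in sorted(finished, key=lambda p: p.pid)
        if len(p.frames) >= 2
    ]
    logger.info("linked %d trajectories", len(tracks))
    return tracks


def filter_trajectories(
    tracks: Sequence[Trajectory], min_duration: float
) -> list[Trajectory]:
    """Keep tracks whose recorded duration reaches ``min_duration`` seconds.

    Duration is elapsed time between first and last observation,
    ``(last_frame - first_frame) / frame_rate``. Order is preserved.
    """
    if min_duration < 0:
        raise ValueError("min_duration must be >= 0")
    kept = [t for t in tracks if t.duration >= min_duration - 1e-12]
    if tracks and not kept:
        logger.warning(
            "all %d trajectories shorter than %.3g s were removed", len(tracks), min_duration
        )
    else:
        logger.info("kept %d/%d trajectories >= %.3g s", len(kept), len(tracks), min_duration)
    return kept
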